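"""Multi-scale texture filter bank and per-pixel feature stacks.

The bank follows the classic texture-segmentation design: at each scale σ it
holds ``n_orientations`` odd-symmetric and ``n_orientations`` even-symmetric
oriented Gaussian-derivative kernels (orientations evenly spaced over
[0°, 180°)) plus four rotation-invariant members — two plain Gaussians and two
Laplacian-of-Gaussian kernels at σ/2 and σ. With the default four scales
σ = {16, 24, 32, 48} px and five orientations that is 14 kernels per scale,
56 in total, and 3 × 56 = 168 features per pixel for an L*a*b* image.

Even-symmetric kernels are the second derivative of a 3:1 elongated Gaussian
across its short axis; odd-symmetric kernels are the Hilbert-transform pair of
the even ones (closed form via the Dawson function). Zero-mean families are
L1-normalized so response magnitudes are comparable across scales; plain
Gaussians sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import dawsn

from .scene_io import LabScene

DEFAULT_SCALES = (16.0, 24.0, 32.0, 48.0)
DEFAULT_N_ORIENTATIONS = 5

#: long-axis : short-axis ratio of the oriented elongated Gaussians
ORIENTED_ASPECT = 3.0


@dataclass
class FilterKernel:
    array: np.ndarray
    scale: float
    family: str  # "odd-deriv" | "even-deriv" | "gaussian" | "log"
    orientation: float | str  # degrees, or "rotinv"


@dataclass
class FilterBank:
    kernels: list[FilterKernel]
    scales: tuple[float, ...]
    n_orientations: int

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def max_halfwidth(self) -> int:
        return max(k.array.shape[0] // 2 for k in self.kernels)


@dataclass
class FeatureStack:
    """Per-pixel filter responses: H x W x (3 x bank size)."""

    features: np.ndarray
    channel_order: list[str] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return self.features.shape[2]


def _window_coords(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    # window rule: half-width 2σ rounded up -> >4σ total support
    half = int(np.ceil(2 * sigma))
    r = np.arange(-half, half + 1, dtype=float)
    return np.meshgrid(r, r, indexing="ij")  # (y, x)


def _gauss1d(u: np.ndarray, s: float) -> np.ndarray:
    return np.exp(-(u**2) / (2 * s**2))


def _gauss1d_d2(u: np.ndarray, s: float) -> np.ndarray:
    return (u**2 / s**4 - 1.0 / s**2) * np.exp(-(u**2) / (2 * s**2))


def _hilbert_gauss_d2(u: np.ndarray, s: float) -> np.ndarray:
    # Hilbert pair of the 2nd Gaussian derivative. With D the Dawson function
    # and w = u/(s*sqrt(2)):  H{g}(u) = (2/sqrt(pi)) D(w), and differentiation
    # commutes with the Hilbert transform, so H{g''}(u) = (2/sqrt(pi)) D''(w)/(2 s^2)
    # where D' = 1 - 2 w D and D'' = -2D - 2w(1 - 2wD).
    w = u / (s * np.sqrt(2.0))
    D = dawsn(w)
    d2 = -2.0 * D - 2.0 * w * (1.0 - 2.0 * w * D)
    return (2.0 / np.sqrt(np.pi)) * d2 / (2.0 * s**2)


def _oriented_kernel(sigma: float, theta_deg: float, odd: bool) -> np.ndarray:
    y, x = _window_coords(sigma)
    th = np.deg2rad(theta_deg)
    u = x * np.cos(th) + y * np.sin(th)  # derivative axis (short)
    v = -x * np.sin(th) + y * np.cos(th)  # bar axis (long)
    s_short = sigma / ORIENTED_ASPECT
    profile = _hilbert_gauss_d2(u, s_short) if odd else _gauss1d_d2(u, s_short)
    k = profile * _gauss1d(v, sigma)
    k -= k.mean()  # enforce exact zero response to constants
    return k / np.abs(k).sum()


def _gaussian_kernel(sigma: float, window_sigma: float) -> np.ndarray:
    y, x = _window_coords(window_sigma)
    k = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    return k / k.sum()


def _log_kernel(sigma: float, window_sigma: float) -> np.ndarray:
    y, x = _window_coords(window_sigma)
    r2 = x**2 + y**2
    k = (r2 - 2 * sigma**2) / sigma**4 * np.exp(-r2 / (2 * sigma**2))
    k -= k.mean()
    return k / np.abs(k).sum()


def build_bank(
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_orientations: int = DEFAULT_N_ORIENTATIONS,
) -> FilterBank:
    """Construct the filter bank: per scale, ``n_orientations`` odd + even
    oriented kernels plus 2 Gaussians and 2 LoGs (at σ/2 and σ).

    Ordering is deterministic: scale-major, then family
    (odd, even, gaussian, log), then orientation ascending.
    """
    if len(scales) == 0:
        raise ValueError("scales must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")

    thetas = np.arange(n_orientations) * 180.0 / n_orientations
    kernels: list[FilterKernel] = []
    for sigma in scales:
        for th in thetas:
            kernels.append(FilterKernel(_oriented_kernel(sigma, th, odd=True),
                                        sigma, "odd-deriv", float(th)))
        for th in thetas:
            kernels.append(FilterKernel(_oriented_kernel(sigma, th, odd=False),
                                        sigma, "even-deriv", float(th)))
        for sub in (sigma / 2.0, sigma):
            kernels.append(FilterKernel(_gaussian_kernel(sub, sigma), sigma,
                                        "gaussian", "rotinv"))
        for sub in (sigma / 2.0, sigma):
            kernels.append(FilterKernel(_log_kernel(sub, sigma), sigma,
                                        "log", "rotinv"))
    return FilterBank(kernels=kernels, scales=tuple(scales),
                      n_orientations=n_orientations)


def convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Spatial convolution with reflect (mirror, edge not repeated) padding.

    Computed by FFT on a reflect-padded copy; identical to direct summation
    because the pad width covers the kernel half-width.
    """
    half = kernel.shape[0] // 2
    if image.shape[0] <= half or image.shape[1] <= half:
        raise ValueError(
            f"image {image.shape} smaller than kernel half-width {half}"
        )
    padded = np.pad(image, half, mode="reflect")
    out = fftconvolve(padded, kernel, mode="same")
    return out[half:-half, half:-half] if half else out


def apply_bank(scene: LabScene, bank: FilterBank,
               standardize: bool = False) -> FeatureStack:
    """Convolve each of L, a, b with every kernel -> H x W x (3·|bank|) stack.

    ``standardize`` optionally z-scores each feature map before clustering
    (off by default).
    """
    channels = [("L", scene.L), ("a", scene.a), ("b", scene.b)]
    maps = []
    order = []
    for name, chan in channels:
        if not np.isfinite(chan).all():
            raise ValueError(f"channel {name} contains non-finite values")
        for i, k in enumerate(bank.kernels):
            maps.append(convolve_reflect(chan, k.array))
            order.append(f"{name}:{k.family}:s{k.scale:g}:o{k.orientation}")
    feats = np.stack(maps, axis=-1)
    if standardize:
        mu = feats.mean(axis=(0, 1), keepdims=True)
        sd = feats.std(axis=(0, 1), keepdims=True)
        sd[sd == 0] = 1.0
        feats = (feats - mu) / sd
    return FeatureStack(features=feats, channel_order=order)
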