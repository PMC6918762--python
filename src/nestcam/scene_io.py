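"""Scene ingestion: raster images + ROI masks, gray-standard normalization, Lab conversion.

Images are expected as *linear* RGB rasters (16-bit TIFF/PNG or float arrays in
[0, 1]).  RAW sensor decoding is out of scope; :func:`load_scene` accepts an
optional ``raw_reader`` hook for callers who decode RAW elsewhere.

Region-of-interest masks use integer codes:

====  ==========================================
code  region
====  ==========================================
0     excluded margin (not analyzed)
1     egg area (all eggs)
2     nest area
3     internal buffer ring (clustered, unscored)
4     external area / microhabitat
====  ==========================================
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage
from skimage import color as skcolor
from skimage import draw as skdraw
from skimage import measure

MARGIN = 0
EGG = 1
NEST = 2
INTERNAL = 3
EXTERNAL = 4

VALID_CODES = frozenset({MARGIN, EGG, NEST, INTERNAL, EXTERNAL})

#: linear sRGB -> CIE XYZ, D65 white (IEC 61966-2-1). skimage's rgb2xyz applies
#: the sRGB transfer function first, which is wrong for linear input, so the
#: matrix is applied directly here.
_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ2RGB = np.linalg.inv(_RGB2XYZ)


@dataclass
class GrayStandard:
    """Reference patch of known reflectance used to normalize exposures.

    The field protocol photographs a gray card of 18% nominal reflectance;
    dividing linear pixel values by the card's measured value and multiplying
    by 0.18 puts the image in absolute reflectance units.
    """

    measured_value: float
    nominal_reflectance: float = 0.18

    def __post_init__(self) -> None:
        if not self.measured_value > 0:
            raise ValueError("gray standard measured_value must be > 0")
        if not 0 < self.nominal_reflectance < 1:
            raise ValueError("nominal_reflectance must lie in (0, 1)")


@dataclass
class RegionMask:
    """Per-pixel ROI codes plus per-egg instance labels and lengths."""

    labels: np.ndarray  # H x W int, codes in VALID_CODES
    egg_instances: np.ndarray | None = None  # H x W int, 0 = not egg
    egg_lengths_px: np.ndarray | None = None  # per instance, major-axis length

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        bad = set(np.unique(self.labels)) - VALID_CODES
        if bad:
            raise ValueError(f"unknown region code(s): {sorted(bad)}")
        if self.egg_instances is None and (self.labels == EGG).any():
            self._derive_egg_instances()

    def _derive_egg_instances(self) -> None:
        inst, _ = ndimage.label(self.labels == EGG)
        self.egg_instances = inst
        lengths = []
        for p in measure.regionprops(inst):
            lengths.append(p.axis_major_length)
        self.egg_lengths_px = np.asarray(lengths)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_pixels(self, code: int) -> np.ndarray:
        return self.labels == code

    def analyzed(self) -> np.ndarray:
        """Boolean map of pixels that enter the texture analysis (codes 1-4)."""
        return self.labels > 0


@dataclass
class RgbScene:
    """Linear-RGB raster with a physical pixel scale."""

    pixels: np.ndarray  # H x W x 3, linear RGB in [0, 1]
    pixel_scale: float  # mm per pixel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel values must be finite")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be > 0 (mm per pixel)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabScene:
    """Calibrated CIE L*a*b* scene: L* lightness (0-100), a* red/green, b* yellow/blue."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray
    pixel_scale: float
    mask: RegionMask

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape == self.mask.shape):
            raise ValueError("L, a, b and mask must share one H x W shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def channels(self) -> np.ndarray:
        """Stack channels as H x W x 3 in (L, a, b) order."""
        return np.stack([self.L, self.a, self.b], axis=-1)


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Map an integer raster to [0, 1] by its dtype range; floats pass through."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return arr.astype(float)


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def _rasterize_polygons(spec: dict, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon-mask JSON spec to a label image.

    ``spec`` maps are ``{"regions": [{"code": int, "vertices": [[r, c], ...]}]}``
    with 0-based row/col vertex coordinates; later polygons overwrite earlier
    ones, and uncovered pixels default to the external code.
    """
    labels = np.full(shape, EXTERNAL, dtype=int)
    for region in spec["regions"]:
        code = int(region["code"])
        if code not in VALID_CODES:
            raise ValueError(f"unknown region code(s): [{code}]")
        verts = np.asarray(region["vertices"], dtype=float)
        rr, cc = skdraw.polygon(verts[:, 0], verts[:, 1], shape=shape)
        labels[rr, cc] = code
    return labels


def load_scene(
    image_path: str | Path,
    mask_path: str | Path,
    pixel_scale: float,
    raw_reader=None,
) -> tuple[RgbScene, RegionMask]:
    """Load a paired image + ROI mask from disk.

    Parameters
    ----------
    image_path
        Linear 16-bit TIFF/PNG (or 8-bit for quick tests). If ``raw_reader``
        is given it is called with the path and must return a linear H x W x 3
        float array — the hook for callers who decode RAW files externally.
    mask_path
        Label raster (PNG/TIFF of region codes) or a ``.json`` polygon file.
    pixel_scale
        Physical scale, mm per pixel.
    """
    if raw_reader is not None:
        pixels = np.asarray(raw_reader(image_path), dtype=float)
    else:
        pixels = _to_unit_float(_read_raster(image_path))
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[2] > 3:  # drop alpha
        pixels = pixels[:, :, :3]

    mask_path = Path(mask_path)
    if mask_path.suffix.lower() == ".json":
        spec = json.loads(mask_path.read_text())
        labels = _rasterize_polygons(spec, pixels.shape[:2])
    else:
        labels = np.asarray(_read_raster(mask_path)).astype(int)
        if labels.ndim == 3:
            labels = labels[:, :, 0]

    if labels.shape != pixels.shape[:2]:
        raise ValueError(
            f"mask dimensions {labels.shape} do not match image {pixels.shape[:2]}"
        )
    scene = RgbScene(pixels=np.clip(pixels, 0.0, 1.0), pixel_scale=pixel_scale,
                     meta={"image_path": str(image_path)})
    return scene, RegionMask(labels=labels)


def exclude_border(mask: RegionMask, margin_fraction: float) -> RegionMask:
    """Recode pixels within ``margin_fraction * min(H, W)`` of any edge to 0.

    Camera optics distort the outermost pixels, so a thin frame is dropped
    from the analysis. Idempotent for a fixed fraction.
    """
    if not 0 <= margin_fraction < 0.5:
        raise ValueError("margin_fraction must lie in [0, 0.5)")
    h, w = mask.shape
    m = int(margin_fraction * min(h, w))
    if m == 0:
        return mask
    labels = mask.labels.copy()
    labels[:m, :] = MARGIN
    labels[-m:, :] = MARGIN
    labels[:, :m] = MARGIN
    labels[:, -m:] = MARGIN
    for code in (EGG, NEST, INTERNAL, EXTERNAL):
        if (mask.labels == code).any() and not (labels == code).any():
            warnings.warn(f"margin exclusion emptied region {code}", stacklevel=2)
    inst = None
    if mask.egg_instances is not None:
        inst = mask.egg_instances.copy()
        inst[labels != EGG] = 0
    return RegionMask(labels=labels, egg_instances=inst,
                      egg_lengths_px=mask.egg_lengths_px)


def _linear_rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    xyz = rgb @ _RGB2XYZ.T
    return skcolor.xyz2lab(xyz)


def lab_to_linear_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of the scene Lab conversion (used by the synthetic generator)."""
    xyz = skcolor.lab2xyz(lab)
    return xyz @ _XYZ2RGB.T


def rgb_to_lab(scene: RgbScene, std: GrayStandard, mask: RegionMask | None = None,
               clip_warn_fraction: float = 0.01) -> LabScene:
    """Normalize by the gray standard and convert to CIE L*a*b*.

    Pixels are scaled so the standard patch maps to its nominal reflectance
    (an 18% card maps to Y = 0.18), making the result invariant to global
    exposure. The white point is D65 under this gray-card adaptation. Linear
    values above 1 after scaling are clipped; heavy clipping indicates
    overexposure and triggers a warning.
    """
    scale = std.nominal_reflectance / std.measured_value
    linear = scene.pixels * scale
    n_clip = int((linear > 1.0).any(axis=-1).sum())
    if n_clip > clip_warn_fraction * linear.shape[0] * linear.shape[1]:
        warnings.warn(
            f"{n_clip} pixels clipped after gray-standard scaling: "
            "possible overexposure", stacklevel=2,
        )
    lab = _linear_rgb_to_lab(np.clip(linear, 0.0, 1.0))
    if mask is None:
        mask = RegionMask(labels=np.full(scene.shape, EXTERNAL, dtype=int))
    return LabScene(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2],
                    pixel_scale=scene.pixel_scale, mask=mask)


def reflectance_of_region(scene: RgbScene, std: GrayStandard, mask: RegionMask,
                          region: int) -> float:
    """Mean reflectance of a region, in absolute units via the gray standard."""
    sel = mask.region_pixels(region)
    if not sel.any():
        raise ValueError(f"region {region} is empty")
    mean_linear = float(scene.pixels[sel].mean())
    return mean_linear / std.measured_value * std.nominal_reflectance
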