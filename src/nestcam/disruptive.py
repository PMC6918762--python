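"""Disruptive-camouflage score: how much of the egg outline the texture
analysis can reconstruct.

The egg borders are dilated with a cross-shaped structuring element whose
radius is 1% of the mean egg length, intersected with the texture-frontier
image, and the intersection thinned back to a single-pixel line. The score is
the percentage of egg-border pixels detected this way; a *lower* score means
the outline blends into the background (better disruptive camouflage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import thin

from .camouflage import TextureMap
from .scene_io import RegionMask

_CROSS4 = ndimage.generate_binary_structure(2, 1)  # 4-connected cross


@dataclass
class DisruptiveScore:
    per_egg: dict[int, float]  # instance id -> % border detected
    scene_value: float  # pooled over all border pixels
    n_border_px: int
    radius_px: int


def egg_border_image(mask: RegionMask) -> np.ndarray:
    """One-pixel-wide inner outline of every egg instance."""
    if mask.egg_instances is None or not (mask.egg_instances > 0).any():
        raise ValueError("mask contains no egg instances")
    inst = mask.egg_instances
    border = np.zeros(inst.shape, dtype=bool)
    for i in np.unique(inst[inst > 0]):
        m = inst == i
        border |= m & ~ndimage.binary_erosion(m, structure=_CROSS4,
                                              border_value=0)
    return border


def cross_element(radius: int) -> np.ndarray:
    """Plus-shaped structuring element of the given arm radius."""
    size = 2 * radius + 1
    el = np.zeros((size, size), dtype=bool)
    el[radius, :] = True
    el[:, radius] = True
    return el


def dilation_radius(egg_lengths_px: np.ndarray) -> int:
    """r = round(1% of the arithmetic mean egg length), at least 1 px."""
    lengths = np.asarray(egg_lengths_px, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("egg lengths must be positive")
    return max(1, int(round(0.01 * lengths.mean())))


def dilate_border(border: np.ndarray, egg_lengths_px: np.ndarray) -> np.ndarray:
    """Dilate the egg-border image with the cross element sized from egg length."""
    r = dilation_radius(egg_lengths_px)
    return ndimage.binary_dilation(border, structure=cross_element(r))


def disruptive_score(tex: TextureMap, mask: RegionMask) -> DisruptiveScore:
    """Percentage of egg-border pixels that coincide with texture boundaries.

    A border pixel counts as detected when a thinned intersection pixel lies
    within the dilation radius of it; each border pixel counts at most once,
    keeping the score in [0, 100]. Multiple eggs are pooled over all border
    pixels for the scene value; per-egg values are reported alongside.
    """
    border = egg_border_image(mask)
    n_border = int(border.sum())
    if n_border == 0:
        raise ValueError("egg border has zero length")
    if mask.egg_lengths_px is None:
        raise ValueError("mask lacks egg lengths")
    r = dilation_radius(mask.egg_lengths_px)
    dilated = ndimage.binary_dilation(border, structure=cross_element(r))
    intersection = dilated & tex.boundaries
    thinned = thin(intersection)

    detected = np.zeros_like(border)
    if thinned.any():
        dist_to_thinned = ndimage.distance_transform_edt(~thinned)
        # +0.5 admits diagonal adjacency at radius 1
        detected = border & (dist_to_thinned <= r + 0.5)

    per_egg: dict[int, float] = {}
    inst = mask.egg_instances
    for i in np.unique(inst[inst > 0]):
        b = border & (inst == i)
        per_egg[int(i)] = 100.0 * detected[b].sum() / b.sum()
    return DisruptiveScore(
        per_egg=per_egg,
        scene_value=100.0 * float(detected[border].sum()) / n_border,
        n_border_px=n_border,
        radius_px=r,
    )
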