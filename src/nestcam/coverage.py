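"""Nest-material coverage from a close-up photo: a digital grid of physical
squares (default 2 x 2 mm) laid over the nest ROI; a square counts as
*dominated* when the experimental material covers more than half of it.

The percentage of dominated squares measures how much added material the
birds accepted. Material masks are inputs (manual or synthetic); automatic
material segmentation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_SQUARE_MM = 2.0


@dataclass
class CoverageResult:
    n_squares: int  # grid squares counted as inside the nest
    n_dominated: int  # squares with material on >50% of their in-nest area
    percent: float
    square_px: int


def coverage_percent(
    material_mask: np.ndarray,
    nest_mask: np.ndarray,
    pixel_scale: float,
    square_mm: float = DEFAULT_SQUARE_MM,
) -> CoverageResult:
    """Grid-based material coverage of the nest surface.

    The grid is anchored at the nest bounding-box corner. A square belongs to
    the nest when at least 50% of its area lies inside the nest mask; it is
    dominated when material pixels exceed 50% of its in-nest area.
    """
    material_mask = np.asarray(material_mask, dtype=bool)
    nest_mask = np.asarray(nest_mask, dtype=bool)
    if material_mask.shape != nest_mask.shape:
        raise ValueError("material and nest masks must have the same shape")
    if pixel_scale <= 0 or square_mm <= 0:
        raise ValueError("pixel_scale and square_mm must be positive")
    if not nest_mask.any():
        raise ValueError("nest mask is empty")
    s = int(round(square_mm / pixel_scale))
    if s < 1:
        raise ValueError(
            f"grid square of {square_mm} mm is smaller than one pixel at "
            f"{pixel_scale} mm/px"
        )

    rows = np.nonzero(nest_mask.any(axis=1))[0]
    cols = np.nonzero(nest_mask.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1

    n_squares = 0
    n_dominated = 0
    area = s * s
    for rr in range(r0, r1, s):
        for cc in range(c0, c1, s):
            nest_sq = nest_mask[rr:rr + s, cc:cc + s]
            in_nest = int(nest_sq.sum())
            if in_nest * 2 < area:  # <50% of the square inside the nest
                continue
            n_squares += 1
            mat = int((material_mask[rr:rr + s, cc:cc + s] & nest_sq).sum())
            if mat * 2 > in_nest:
                n_dominated += 1
    percent = 100.0 * n_dominated / n_squares if n_squares else 0.0
    return CoverageResult(n_squares=n_squares, n_dominated=n_dominated,
                          percent=percent, square_px=s)
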