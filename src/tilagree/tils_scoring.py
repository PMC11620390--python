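"""TILs score from one observer's stromal mask and lymphocyte points.

The stromal TILs score is the fraction of stromal area occupied by
lymphocytes:

    T = (L · a_lymph) / (stromal pixel count · pixel_size²)

where L is the number of annotated lymphocytes whose center falls inside
stroma and a_lymph is the fixed per-cell area derived from the accepted
average lymphocyte diameter of 8 μm (π·(d/2)² ≈ 50.3 μm²).  Only point
centers are annotated, so cell membership is decided by the center pixel
(rounded coordinates).  T is not capped at 1; implausible values > 1 raise
a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io_annotations import MaskStack, PointSets

__all__ = [
    "DEFAULT_PIXEL_SIZE_UM",
    "LYMPH_DIAMETER_UM",
    "LYMPH_AREA_UM2",
    "TilsResult",
    "lymphocyte_area_from_diameter",
    "tils_score",
    "tils_per_observer",
]

#: Derived from a 3000×3000-px field covering ~0.476 mm²: √(0.476e6/9e6) ≈ 0.23.
DEFAULT_PIXEL_SIZE_UM = 0.23
LYMPH_DIAMETER_UM = 8.0
LYMPH_AREA_UM2 = 50.3


def lymphocyte_area_from_diameter(diameter_um: float) -> float:
    """Circular cell area π·(d/2)² in μm² from a diameter in μm."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * (diameter_um / 2.0) ** 2


@dataclass
class TilsResult:
    """One observer's TILs score with its ingredients."""

    t: float
    stromal_area_um2: float
    stromal_lymphocyte_count: int
    excluded_point_count: int
    pixel_size_um: float
    lymph_area_um2: float


def tils_score(
    mask: np.ndarray,
    points: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    lymph_area_um2: float = LYMPH_AREA_UM2,
) -> TilsResult:
    """TILs score for one observer.

    Parameters
    ----------
    mask : (H, W) binary array, 1 = stroma.
    points : (m, 2) array of (x, y) lymphocyte centers in pixels.
    pixel_size_um : physical pixel side in μm.
    lymph_area_um2 : fixed area attributed to each stromal lymphocyte.
    """
    if pixel_size_um <= 0 or lymph_area_um2 <= 0:
        raise ValueError("pixel_size_um and lymph_area_um2 must be positive")
    mask = np.asarray(mask)
    stroma_px = int((mask > 0).sum())
    if stroma_px == 0:
        raise ValueError("no stroma to score: mask has zero stromal pixels")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    h, w = mask.shape
    in_stroma = 0
    for x, y in pts:
        col, row = int(round(x)), int(round(y))
        if 0 <= row < h and 0 <= col < w and mask[row, col] > 0:
            in_stroma += 1
    stromal_area = stroma_px * pixel_size_um**2
    t = in_stroma * lymph_area_um2 / stromal_area
    if t > 1:
        warnings.warn(f"TILs score {t:.3f} exceeds 1", stacklevel=2)
    return TilsResult(
        t=float(t),
        stromal_area_um2=float(stromal_area),
        stromal_lymphocyte_count=in_stroma,
        excluded_point_count=len(pts) - in_stroma,
        pixel_size_um=pixel_size_um,
        lymph_area_um2=lymph_area_um2,
    )


def tils_per_observer(
    stack: MaskStack,
    points: PointSets,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    lymph_area_um2: float = LYMPH_AREA_UM2,
) -> list[TilsResult]:
    """Observer-wise TILs scores: observer i's own mask with their own points."""
    if stack.observer_ids != points.observer_ids:
        raise ValueError("mask stack and point sets list different observers")
    return [
        tils_score(mask, pts, pixel_size_um=pixel_size_um,
                   lymph_area_um2=lymph_area_um2)
        for mask, pts in zip(stack.masks, points.points)
    ]
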