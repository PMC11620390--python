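"""Sensitivity analyses for the agreement measures.

The mask "shift test" simulates small boundary errors by displacing
observers' masks by controlled random offsets and tracks how plain and
boundary-weighted Fleiss' kappa respond; the gain percentage
100·(BWFK−FK)/FK quantifies the benefit of boundary weighting.  The point
"shift test" jitters cell coordinates within a bounded range, and the
"lost test" removes a fraction of points, probing the distance-based cell
agreement score's robustness to localisation error and missed detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_agreement import DbcaaConfig, dbcaa
from .io_annotations import MaskStack, PointSets
from .kappa_agreement import DEFAULT_DT, bwfk, fleiss_kappa, build_count_table

__all__ = [
    "ShiftTestResult",
    "PointPerturbResult",
    "shift_mask",
    "mask_shift_test",
    "point_shift_test",
    "point_lost_test",
]


@dataclass
class ShiftTestResult:
    shifts: np.ndarray
    fk: np.ndarray
    bwfk: np.ndarray
    gain_pct: np.ndarray
    dt: float
    seed: int | None


@dataclass
class PointPerturbResult:
    levels: np.ndarray  # pixels (shift) or fractions (lost)
    scores: np.ndarray
    mode: str  # "shift" | "lost"
    seed: int | None


def shift_mask(
    mask: np.ndarray, dx: int, dy: int, fill: int = 0, wrap: bool = False
) -> np.ndarray:
    """Translate a binary mask by (dx, dy) pixels (x = columns, y = rows).

    Output dimensions are unchanged; vacated pixels take ``fill``
    (non-stroma by default) unless ``wrap`` is set.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"shift ({dx}, {dy}) exceeds image size {w}x{h}")
    if wrap:
        return np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
    out = np.full_like(mask, fill)
    src_r = slice(max(0, -dy), h - max(0, dy))
    src_c = slice(max(0, -dx), w - max(0, dx))
    dst_r = slice(max(0, dy), h - max(0, -dy))
    dst_c = slice(max(0, dx), w - max(0, -dx))
    out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def _random_offset(rng: np.random.Generator, magnitude: float) -> tuple[int, int]:
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return int(round(magnitude * np.cos(theta))), int(round(magnitude * np.sin(theta)))


def mask_shift_test(
    stack: MaskStack,
    shifts,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    shift_all: bool = True,
    wrap: bool = False,
) -> ShiftTestResult:
    """FK, BWFK and gain % as observers' masks are displaced.

    For each shift magnitude, every observer's mask (or only the first, with
    ``shift_all=False``) is displaced in an independently drawn uniform
    random direction.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    shifts = np.asarray(list(shifts), dtype=float)
    fk_vals, bw_vals = [], []
    for s in shifts:
        masks = []
        for i, mask in enumerate(stack.masks):
            if s == 0 or (not shift_all and i > 0):
                masks.append(mask)
            else:
                dx, dy = _random_offset(rng, s)
                masks.append(shift_mask(mask, dx, dy, wrap=wrap))
        shifted = MaskStack(
            masks=np.stack(masks), observer_ids=list(stack.observer_ids),
            image_id=stack.image_id, exclusion=stack.exclusion,
        )
        fk_vals.append(fleiss_kappa(build_count_table(shifted)).kappa)
        bw_vals.append(bwfk(shifted, dt=dt).kappa)
    fk_arr = np.asarray(fk_vals)
    bw_arr = np.asarray(bw_vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = 100.0 * (bw_arr - fk_arr) / fk_arr
    return ShiftTestResult(
        shifts=shifts, fk=fk_arr, bwfk=bw_arr, gain_pct=gain, dt=dt, seed=seed
    )


def point_shift_test(
    points: PointSets,
    max_shifts,
    config: DbcaaConfig,
    seed: int | None = None,
) -> PointPerturbResult:
    """Cell agreement as coordinates are jittered within a bounded range.

    At level r, every point is displaced by an independent offset drawn
    uniformly from the disk of radius r (so the displacement magnitude
    never exceeds r), and the agreement score is recomputed.  Points that
    coincide across observers therefore cannot drift further than 2r
    apart, which pins the onset of score degradation at r ≈ D_L/2 for
    well-separated perfect-agreement sets.
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(list(max_shifts), dtype=float)
    scores = []
    for r in levels:
        perturbed = []
        for pts in points.points:
            if len(pts) and r > 0:
                theta = rng.uniform(0, 2 * np.pi, len(pts))
                rad = r * np.sqrt(rng.uniform(0, 1, len(pts)))
                offs = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
                perturbed.append(pts + offs)
            else:
                perturbed.append(pts)
        ps = PointSets(
            points=perturbed, observer_ids=list(points.observer_ids),
            image_id=points.image_id,
        )
        scores.append(dbcaa(ps, config).score)
    return PointPerturbResult(
        levels=levels, scores=np.asarray(scores), mode="shift", seed=seed
    )


def point_lost_test(
    points: PointSets,
    fractions,
    config: DbcaaConfig,
    seed: int | None = None,
) -> PointPerturbResult:
    """Cell agreement as a fraction of points is removed per observer.

    At fraction f, ⌊f·m_i⌋ points are removed uniformly at random from each
    observer, and the agreement score is recomputed.  Removing every point
    (f so large that no points survive) is a contract violation.
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(list(fractions), dtype=float)
    if (levels < 0).any() or (levels > 1).any():
        raise ValueError("fractions must lie in [0, 1]")
    scores = []
    for f in levels:
        kept = []
        for pts in points.points:
            m = len(pts)
            n_drop = int(np.floor(f * m))
            keep_idx = rng.permutation(m)[: m - n_drop]
            kept.append(pts[np.sort(keep_idx)])
        if sum(len(k) for k in kept) == 0:
            raise ValueError(f"fraction {f} removes every point; score undefined")
        ps = PointSets(
            points=kept, observer_ids=list(points.observer_ids),
            image_id=points.image_id,
        )
        scores.append(dbcaa(ps, config).score)
    return PointPerturbResult(
        levels=levels, scores=np.asarray(scores), mode="lost", seed=seed
    )
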