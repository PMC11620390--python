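"""Distance-Based Cell Agreement Algorithm (DBCAA).

Ground-truth-free agreement over per-observer cell center points.  For each
annotated point P of observer i, count the other observers j whose nearest
point to P lies within the expected lymphocyte diameter ``d_l``; the
agreement score is the grand total of those counters over a normalising
denominator.

Two normalisations are provided.  The literal algorithm divides by
``N·Σm_i``, under which even identical annotations score (N−1)/N.  The
default ``max_match`` divides by ``(N−1)·Σm_i`` — the maximum attainable
total — so perfect agreement scores 1.0.

Matching is one-to-many: several points of observer i may match the same
point of observer j; no exclusivity constraint is imposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_annotations import PointSets

__all__ = [
    "DbcaaConfig",
    "DbcaaResult",
    "nearest_point_distance",
    "dbcaa",
    "dbcaa_brute_force",
    "render_agreement_counts",
]

#: Lymphocyte diameter in micrometres used to derive the default match radius.
LYMPHOCYTE_DIAMETER_UM = 8.0


@dataclass(frozen=True)
class DbcaaConfig:
    """Parameters of the agreement computation.

    d_l : float
        Expected lymphocyte diameter in pixels; the match radius.
    normalization : {"max_match", "paper"}
        Denominator choice: ``(N−1)·Σm_i`` (default; perfect agreement = 1)
        or the literal ``N·Σm_i``.
    strict_inequality : bool
        Match when distance < d_l (default) or ≤ d_l.
    """

    d_l: float
    normalization: str = "max_match"
    strict_inequality: bool = True

    def __post_init__(self) -> None:
        if self.d_l <= 0:
            raise ValueError("d_l must be positive")
        if self.normalization not in {"max_match", "paper"}:
            raise ValueError("normalization must be 'max_match' or 'paper'")

    @classmethod
    def from_physical(
        cls, pixel_size_um: float, diameter_um: float = LYMPHOCYTE_DIAMETER_UM, **kw
    ) -> "DbcaaConfig":
        """Build a config from physical calibration (μm per pixel)."""
        if pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        return cls(d_l=diameter_um / pixel_size_um, **kw)


@dataclass
class DbcaaResult:
    """Agreement score plus the per-point counters behind it.

    ``counters[i][k]`` is the number of other observers with a point within
    d_l of the k-th point of observer i (0 ≤ value ≤ N−1).
    """

    score: float
    counters: list[np.ndarray]
    n_observers: int
    total_points: int
    config: DbcaaConfig

    @property
    def per_observer_totals(self) -> np.ndarray:
        return np.array([c.sum() for c in self.counters])


def nearest_point_distance(p, points) -> float:
    """Euclidean distance from ``p`` to the nearest point of a sequence.

    An empty sequence yields +inf (no possible match).
    """
    arr = np.asarray(points, dtype=float).reshape(-1, 2)
    if arr.shape[0] == 0:
        return float("inf")
    d = arr - np.asarray(p, dtype=float)
    return float(np.sqrt((d**2).sum(axis=1)).min())


def _counters(points: list[np.ndarray], config: DbcaaConfig) -> list[np.ndarray]:
    trees = [cKDTree(p) if len(p) else None for p in points]
    out = []
    for i, pts_i in enumerate(points):
        cnt = np.zeros(len(pts_i), dtype=np.int64)
        if len(pts_i):
            for j, tree in enumerate(trees):
                if j == i or tree is None:
                    continue
                dmin, _ = tree.query(pts_i)
                cnt += (
                    (dmin < config.d_l)
                    if config.strict_inequality
                    else (dmin <= config.d_l)
                )
        out.append(cnt)
    return out


def dbcaa(points: PointSets, config: DbcaaConfig) -> DbcaaResult:
    """Compute the cell-detection agreement score among N observers.

    Uses a k-d tree for the nearest-point queries; results are identical to
    the all-pairs computation (:func:`dbcaa_brute_force`).
    """
    n = points.n_observers
    if n < 2:
        raise ValueError("DBCAA needs at least 2 observers")
    for obs_id, m in zip(points.observer_ids, points.counts):
        if m == 0:
            warnings.warn(
                f"observer {obs_id!r} has no points; contributes nothing",
                stacklevel=2,
            )
    total_m = points.total_points
    counters = _counters(points.points, config)
    total_a = int(sum(c.sum() for c in counters))
    z = (n if config.normalization == "paper" else n - 1) * total_m
    score = total_a / z if z else 0.0
    return DbcaaResult(
        score=float(score), counters=counters, n_observers=n,
        total_points=total_m, config=config,
    )


def dbcaa_brute_force(points: PointSets, config: DbcaaConfig) -> DbcaaResult:
    """All-pairs reference implementation (no spatial index)."""
    n = points.n_observers
    if n < 2:
        raise ValueError("DBCAA needs at least 2 observers")
    counters = []
    for i, pts_i in enumerate(points.points):
        cnt = np.zeros(len(pts_i), dtype=np.int64)
        for k, p in enumerate(pts_i):
            for j, pts_j in enumerate(points.points):
                if j == i:
                    continue
                dmin = nearest_point_distance(p, pts_j)
                hit = dmin < config.d_l if config.strict_inequality else dmin <= config.d_l
                cnt[k] += hit
        counters.append(cnt)
    total_m = points.total_points
    total_a = int(sum(c.sum() for c in counters))
    z = (n if config.normalization == "paper" else n - 1) * total_m
    return DbcaaResult(
        score=float(total_a / z) if z else 0.0, counters=counters,
        n_observers=n, total_points=total_m, config=config,
    )


_OBSERVER_COLORS = [
    (0.86, 0.08, 0.24),  # red
    (0.00, 0.60, 0.09),  # green
    (0.00, 0.75, 0.75),  # aqua
    (0.93, 0.79, 0.00),  # yellow
    (0.48, 0.25, 0.80),
    (0.95, 0.52, 0.00),
]


def render_agreement_counts(
    points: PointSets,
    result: DbcaaResult,
    image: np.ndarray | None = None,
    ax=None,
):
    """Draw each observer's points in a distinct color, labelled with their
    agreement counters.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    if image is not None:
        ax.imshow(image, cmap="gray")
    elif points.frame is not None:
        h, w = points.frame
        ax.set_xlim(0, w)
        ax.set_ylim(h, 0)
    for i, (obs_id, pts) in enumerate(zip(points.observer_ids, points.points)):
        color = _OBSERVER_COLORS[i % len(_OBSERVER_COLORS)]
        if len(pts):
            ax.scatter(pts[:, 0], pts[:, 1], s=18, color=color, label=obs_id)
            for (x, y), a in zip(pts, result.counters[i]):
                ax.annotate(str(int(a)), (x, y), fontsize=7, color=color,
                            xytext=(2, 2), textcoords="offset points")
    ax.set_aspect("equal")
    if points.n_observers:
        ax.legend(fontsize=7, loc="upper right")
    ax.set_title(f"DBCAA = {result.score:.3f}")
    return ax
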