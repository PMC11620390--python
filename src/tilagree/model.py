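"""Model/Results interface over the agreement measures.

Three model classes mirror the three levels at which observers can agree:

* :class:`SegmentationAgreement` — pixel-wise agreement on binary stromal
  masks (Fleiss' kappa and its boundary-weighted variant);
* :class:`CellDetectionAgreement` — ground-truth-free agreement on cell
  center points (distance-based cell agreement);
* :class:`TilsConcordance` — concordance of the derived continuous TILs
  scores (ICC, multi-observer Bland-Altman limits).

Each model is built from data, ``fit()`` returns a Results object carrying
the estimates and diagnostics with a ``summary()`` table, and the
sensitivity simulations hang off the model objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cell_agreement as ca
from . import concordance_stats as cs
from . import kappa_agreement as ka
from . import sensitivity as sens
from . import tils_scoring as ts
from .io_annotations import MaskStack, PointSets

__all__ = [
    "SegmentationAgreement",
    "SegmentationAgreementResults",
    "CellDetectionAgreement",
    "CellDetectionAgreementResults",
    "TilsConcordance",
    "TilsConcordanceResults",
]


def _fmt_table(title: str, rows: list[tuple[str, object]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * max(len(title), width + 12)]
    for key, val in rows:
        if isinstance(val, float):
            val = f"{val:.6g}"
        lines.append(f"{key:<{width}}{val}")
    return "\n".join(lines)


class SegmentationAgreement:
    """Pixel-wise inter-observer agreement model for binary stromal masks.

    Parameters
    ----------
    stack : MaskStack
        Aligned per-observer binary masks.
    dt : float
        Flattening threshold of the boundary distance map in pixels.
    exclusion : array, optional
        Extra boolean mask of pixels to drop from the universe.
    """

    def __init__(self, stack: MaskStack, dt: float = ka.DEFAULT_DT,
                 exclusion: np.ndarray | None = None,
                 clip_before_average: bool = False):
        self.stack = stack
        self.dt = dt
        self.exclusion = exclusion
        self.clip_before_average = clip_before_average

    def fit(self) -> "SegmentationAgreementResults":
        table = ka.build_count_table(self.stack, self.exclusion)
        fk = ka.fleiss_kappa(table)
        weight_map = ka.boundary_weight_map(
            self.stack, dt=self.dt, exclusion=self.exclusion,
            clip_before_average=self.clip_before_average,
        )
        bw = ka.bwfk(self.stack, dt=self.dt, exclusion=self.exclusion,
                     weight_map=weight_map)
        return SegmentationAgreementResults(
            model=self, fk=fk, bwfk=bw, count_table=table, weight_map=weight_map
        )

    def agreement_maps(self) -> ka.AgreementMaps:
        return ka.agreement_maps(self.stack)

    def shift_test(self, shifts, seed: int | None = None,
                   shift_all: bool = True) -> sens.ShiftTestResult:
        """Displace observers' masks and track FK/BWFK robustness."""
        return sens.mask_shift_test(self.stack, shifts, dt=self.dt, seed=seed,
                                    shift_all=shift_all)


@dataclass
class SegmentationAgreementResults:
    model: SegmentationAgreement
    fk: ka.KappaResult
    bwfk: ka.KappaResult
    count_table: ka.AgreementCountTable
    weight_map: ka.WeightMap

    @property
    def gain_pct(self) -> float:
        """Percentage gain of boundary weighting over the plain kappa."""
        return 100.0 * (self.bwfk.kappa - self.fk.kappa) / self.fk.kappa

    def summary(self) -> str:
        rows = [
            ("Image", self.model.stack.image_id or "<unnamed>"),
            ("Observers (N)", self.fk.n_observers),
            ("Pixels in universe (M)", self.fk.n_pixels),
            ("Fleiss' kappa (FK)", self.fk.kappa),
            ("  observed agreement Po", self.fk.p_observed),
            ("  expected agreement Pe", self.fk.p_expected),
            ("Boundary-weighted kappa (BWFK)", self.bwfk.kappa),
            ("  weighted Po", self.bwfk.p_observed),
            ("  weighted Pe", self.bwfk.p_expected),
            ("Flattening threshold DT (px)", self.model.dt),
            ("BWFK gain (%)", self.gain_pct),
        ]
        if self.fk.degenerate or self.bwfk.degenerate:
            rows.append(("Degenerate universe", True))
        return _fmt_table("Segmentation agreement", rows)


class CellDetectionAgreement:
    """Ground-truth-free agreement model for point-annotated cells.

    The match radius ``d_l`` (expected lymphocyte diameter, pixels) is
    either given directly or derived from physical calibration as
    8 μm / pixel_size_um.
    """

    def __init__(self, points: PointSets, d_l: float | None = None,
                 pixel_size_um: float | None = None,
                 normalization: str = "max_match",
                 strict_inequality: bool = True):
        if d_l is None:
            if pixel_size_um is None:
                raise ValueError("give d_l in pixels or pixel_size_um for 8 μm")
            config = ca.DbcaaConfig.from_physical(
                pixel_size_um, normalization=normalization,
                strict_inequality=strict_inequality,
            )
        else:
            config = ca.DbcaaConfig(
                d_l=d_l, normalization=normalization,
                strict_inequality=strict_inequality,
            )
        self.points = points
        self.config = config

    def fit(self) -> "CellDetectionAgreementResults":
        return CellDetectionAgreementResults(
            model=self, result=ca.dbcaa(self.points, self.config)
        )

    def shift_test(self, max_shifts, seed: int | None = None) -> sens.PointPerturbResult:
        return sens.point_shift_test(self.points, max_shifts, self.config, seed=seed)

    def lost_test(self, fractions, seed: int | None = None) -> sens.PointPerturbResult:
        return sens.point_lost_test(self.points, fractions, self.config, seed=seed)


@dataclass
class CellDetectionAgreementResults:
    model: CellDetectionAgreement
    result: ca.DbcaaResult

    @property
    def score(self) -> float:
        return self.result.score

    def summary(self) -> str:
        cfg = self.model.config
        rows = [
            ("Image", self.model.points.image_id or "<unnamed>"),
            ("Observers (N)", self.result.n_observers),
            ("Total points (Σm)", self.result.total_points),
            ("Match radius D_L (px)", cfg.d_l),
            ("Normalization", cfg.normalization),
            ("Agreement total (ΣA)", int(sum(c.sum() for c in self.result.counters))),
            ("DBCAA score", self.score),
        ]
        return _fmt_table("Cell detection agreement", rows)

    def plot(self, image: np.ndarray | None = None, ax=None):
        return ca.render_agreement_counts(self.model.points, self.result,
                                          image=image, ax=ax)


class TilsConcordance:
    """Concordance model for per-image, per-observer TILs scores.

    Built either directly from an images × observers score matrix or from
    annotations via :meth:`from_annotations`.
    """

    def __init__(self, scores: pd.DataFrame,
                 icc_model: str = "two_way_random_absolute_single"):
        if not isinstance(scores, pd.DataFrame):
            scores = pd.DataFrame(np.asarray(scores, dtype=float))
        self.scores = scores
        self.icc_model = icc_model

    @classmethod
    def from_annotations(
        cls, stacks: list[MaskStack], point_sets: list[PointSets],
        pixel_size_um: float = ts.DEFAULT_PIXEL_SIZE_UM, **kw,
    ) -> "TilsConcordance":
        rows = {}
        for stack, pts in zip(stacks, point_sets, strict=True):
            results = ts.tils_per_observer(stack, pts, pixel_size_um=pixel_size_um)
            rows[stack.image_id] = {
                obs: r.t for obs, r in zip(stack.observer_ids, results)
            }
        return cls(pd.DataFrame.from_dict(rows, orient="index"), **kw)

    def fit(self) -> "TilsConcordanceResults":
        return TilsConcordanceResults(
            model=self,
            icc=cs.icc(self.scores, model=self.icc_model),
            loam=cs.bland_altman_loam(self.scores),
        )


@dataclass
class TilsConcordanceResults:
    model: TilsConcordance
    icc: cs.IccResult
    loam: cs.LoamResult

    def summary(self) -> str:
        rows = [
            ("Images", self.model.scores.shape[0]),
            ("Observers", self.model.scores.shape[1]),
            ("ICC", self.icc.value),
            ("  model", self.icc.model),
            ("LOAM mean difference", self.loam.mean_difference),
            ("LOAM lower limit", self.loam.lower),
            ("LOAM upper limit", self.loam.upper),
            ("Points outside limits", self.loam.outlier_count),
        ]
        if self.icc.degenerate:
            rows.append(("Degenerate (constant scores)", True))
        return _fmt_table("TILs score concordance", rows)

    def plot_bland_altman(self, ax=None):
        return self.loam.plot(ax=ax)
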