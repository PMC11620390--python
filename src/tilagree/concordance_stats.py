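"""Dataset-level concordance of continuous scores across observers.

Provides the intraclass correlation coefficient from a two-way random
effects ANOVA (absolute agreement, single rater — ICC(2,1)), Bland-Altman
limits of agreement with the mean (LOAM) for multiple observers, Pearson
correlation, and the subgroup correlation test relating segmentation-,
detection- and score-level agreement measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IccResult",
    "LoamResult",
    "CorrelationTestResult",
    "icc",
    "bland_altman_loam",
    "pearson",
    "correlation_test",
]


def _as_matrix(scores) -> np.ndarray:
    arr = np.asarray(
        scores.to_numpy() if isinstance(scores, pd.DataFrame) else scores,
        dtype=float,
    )
    if arr.ndim != 2:
        raise ValueError("scores must be a 2-D images × observers matrix")
    if np.isnan(arr).any():
        raise ValueError("score matrix has missing cells; complete design required")
    return arr


@dataclass
class IccResult:
    value: float
    model: str = "two_way_random_absolute_single"  # ICC(2,1)
    degenerate: bool = False
    ms_rows: float = float("nan")
    ms_cols: float = float("nan")
    ms_error: float = float("nan")

    def __float__(self) -> float:
        return self.value


def icc(scores, model: str = "two_way_random_absolute_single") -> IccResult:
    """Intraclass correlation coefficient over an images × observers matrix.

    Default is the two-way random-effects, absolute-agreement, single-rater
    form, ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n),
    where MSR, MSC, MSE are the row (subject), column (rater) and residual
    mean squares of the two-way ANOVA without replication.
    ``two_way_random_consistency_single`` (ICC(3,1)-style consistency) is
    also available.
    """
    x = _as_matrix(scores)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 images and 2 observers")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if np.allclose(x, x.flat[0]):
        return IccResult(value=1.0, model=model, degenerate=True,
                         ms_rows=msr, ms_cols=msc, ms_error=mse)
    if model == "two_way_random_absolute_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "two_way_random_consistency_single":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    if denom == 0:
        return IccResult(value=1.0, model=model, degenerate=True,
                         ms_rows=msr, ms_cols=msc, ms_error=mse)
    return IccResult(value=float((msr - mse) / denom), model=model,
                     ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse))


@dataclass
class LoamResult:
    """Limits of agreement with the mean for multiple observers.

    ``differences`` holds, for every (image, observer) cell, the deviation
    of that observer's score from the image's across-observer mean;
    ``means`` the corresponding per-image means (repeated per observer).
    Limits are mean difference ± 1.96·SD of the differences.
    """

    mean_difference: float
    sd_difference: float
    lower: float
    upper: float
    means: np.ndarray
    differences: np.ndarray
    outlier_count: int = field(init=False)

    def __post_init__(self) -> None:
        out = (self.differences < self.lower) | (self.differences > self.upper)
        self.outlier_count = int(out.sum())

    def plot(self, ax=None):
        """Bland-Altman style scatter with the mean line and LOAM limits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.means, self.differences, s=12, alpha=0.7)
        ax.axhline(self.mean_difference, color="green", ls=":", label="mean")
        for lim in (self.lower, self.upper):
            ax.axhline(lim, color="red", ls=":")
        ax.set_xlabel("per-image observer mean")
        ax.set_ylabel("difference from mean")
        return ax


def bland_altman_loam(scores) -> LoamResult:
    """Multi-observer Bland-Altman limits of agreement with the mean.

    Roughly 95% of observer-minus-mean differences are expected inside the
    limits when the differences are normally distributed.
    """
    x = _as_matrix(scores)
    if x.shape[1] < 2:
        raise ValueError("LOAM needs at least 2 observers")
    row_means = x.mean(axis=1, keepdims=True)
    diffs = (x - row_means).ravel()
    means = np.repeat(row_means.ravel(), x.shape[1])
    mean_d = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return LoamResult(
        mean_difference=mean_d, sd_difference=sd,
        lower=mean_d - 1.96 * sd, upper=mean_d + 1.96 * sd,
        means=means, differences=diffs,
    )


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationTestResult:
    """Per-subgroup agreement triples and their Pearson correlation matrix."""

    triples: pd.DataFrame  # columns m_s, m_l, m_t; one row per repeat
    r_matrix: pd.DataFrame  # 3×3 Pearson matrix
    subgroup_size: int
    repeats: int
    seed: int | None
    degenerate: bool = False


def correlation_test(
    per_image_ms,
    per_image_ml,
    score_matrix,
    subgroup_size: int = 10,
    repeats: int = 50,
    seed: int | None = None,
) -> CorrelationTestResult:
    """Correlate segmentation, detection and score agreement over subgroups.

    Images are repeatedly sampled into subgroups of ``subgroup_size``
    (without replacement within a repeat, independently across repeats).
    Per subgroup: M_S = mean per-image segmentation agreement (BWFK),
    M_L = mean per-image detection agreement (DBCAA), M_T = ICC of the
    subgroup's TILs score matrix.  The 3×3 Pearson matrix is computed over
    the per-repeat triples.

    Parameters
    ----------
    per_image_ms, per_image_ml : 1-D arrays of per-image agreement values.
    score_matrix : images × observers TILs scores (same image order).
    """
    ms = np.asarray(per_image_ms, dtype=float)
    ml = np.asarray(per_image_ml, dtype=float)
    t = _as_matrix(score_matrix)
    n_images = len(ms)
    if not (len(ml) == n_images == t.shape[0]):
        raise ValueError("per-image inputs must cover the same images")
    if n_images < subgroup_size:
        raise ValueError(
            f"need at least subgroup_size={subgroup_size} images, have {n_images}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(repeats):
        idx = rng.choice(n_images, size=subgroup_size, replace=False)
        rows.append(
            (ms[idx].mean(), ml[idx].mean(), icc(t[idx]).value)
        )
    triples = pd.DataFrame(rows, columns=["m_s", "m_l", "m_t"])
    degenerate = bool((triples.std(ddof=0) == 0).any())
    if degenerate:
        r = pd.DataFrame(
            np.full((3, 3), np.nan), index=triples.columns, columns=triples.columns
        )
        np.fill_diagonal(r.values, 1.0)
    else:
        r = triples.corr(method="pearson")
    return CorrelationTestResult(
        triples=triples, r_matrix=r, subgroup_size=subgroup_size,
        repeats=repeats, seed=seed, degenerate=degenerate,
    )
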