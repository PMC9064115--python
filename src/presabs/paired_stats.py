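"""Paired fold-level comparison of two repeated-CV arms.

Two arms evaluated on the same stratified splits yield a repetitions x folds
matrix of score differences d[j][i]. The comparison statistic averages the
per-repetition fold standard deviations:

    SE = (1/R) * sum_j sigma_j / sqrt(k)
    t  = mean(d) / SE,  df = k - 1 (two-tailed)
    95% CI = mean(d) +/- t_{0.975, k-1} * SE

With k = 10 the CI multiplier is 2.26 (the 0.975 quantile of the t law at
9 degrees of freedom). sigma_j uses the n-1 divisor. The statistic treats
folds within a repetition as independent draws and is known to be
anti-conservative; it bounds rather than attains the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classification import FoldScoreMatrix


@dataclass
class PairedCVDifference:
    """Fold-level differences between two arms sharing a SplitSet."""

    d: np.ndarray  # repetitions x folds

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[1] < 2:
            raise ValueError("difference matrix must be repetitions x folds with k >= 2")
        if np.any(np.isnan(self.d)):
            raise ValueError("difference matrix is incomplete (NaN entries)")

    @classmethod
    def from_fold_scores(
        cls, a: FoldScoreMatrix, b: FoldScoreMatrix, metric: str = "auc"
    ) -> "PairedCVDifference":
        ma, mb = a.scores[metric], b.scores[metric]
        if ma.shape != mb.shape:
            raise ValueError(f"arm shapes differ: {ma.shape} vs {mb.shape}")
        return cls(d=ma - mb)

    @property
    def repetitions(self) -> int:
        return self.d.shape[0]

    @property
    def k(self) -> int:
        return self.d.shape[1]

    @property
    def rep_sd(self) -> np.ndarray:
        """Per-repetition standard deviation sigma_j of the k fold differences."""
        return self.d.std(axis=1, ddof=1)

    @property
    def mean_diff(self) -> float:
        return float(self.d.mean())

    @property
    def standard_error(self) -> float:
        """Repetition-averaged standard error: mean_j(sigma_j) / sqrt(k)."""
        return float(self.rep_sd.mean() / np.sqrt(self.k))


@dataclass(frozen=True)
class PairedComparisonResult:
    mean_diff: float
    ci95: tuple[float, float]
    t_stat: float
    p_value: float
    df: int
    degenerate_spread: bool = False


def t_critical(k: int = 10) -> float:
    """CI multiplier: the 0.975 quantile of the t law at k-1 df (2.26 for k=10)."""
    return float(stats.t.ppf(0.975, df=k - 1))


def paired_ci95(diff: PairedCVDifference) -> tuple[float, float]:
    """95% confidence interval for the mean fold-level difference."""
    half = t_critical(diff.k) * diff.standard_error
    return (diff.mean_diff - half, diff.mean_diff + half)


def paired_t_test(diff: PairedCVDifference) -> PairedComparisonResult:
    """Two-tailed t test of the mean fold-level difference at df = k - 1."""
    se = diff.standard_error
    mean = diff.mean_diff
    df = diff.k - 1
    if se == 0.0:
        if mean == 0.0:
            t_stat, p, degenerate = 0.0, 1.0, False
        else:
            t_stat = np.inf if mean > 0 else -np.inf
            p, degenerate = 0.0, True
    else:
        t_stat = mean / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df=df))
        degenerate = False
    return PairedComparisonResult(
        mean_diff=mean,
        ci95=paired_ci95(diff),
        t_stat=float(t_stat),
        p_value=float(p),
        df=df,
        degenerate_spread=degenerate,
    )
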