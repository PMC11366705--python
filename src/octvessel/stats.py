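"""The study's statistical comparison battery.

Quantitative comparisons use two-sample t-tests (Student pooled-variance by
default, since that is what reproduces the published statistics; Welch is
available), paired t-tests for within-subject contrasts, and Wilcoxon rank
tests when a Shapiro-Wilk gate flags a sample as non-normal.  Qualitative
2x2 comparisons use the Pearson chi-square without continuity correction
(again matching the published values), with Fisher's exact probability
reported alongside whenever an expected cell count drops below 5.  All
tests are two-tailed at alpha 0.05.

Summary-statistic entry points (:func:`pooled_t_from_summary`) allow the
independent-sample statistics to be recomputed directly from printed
mean / SD / n rows; paired statistics cannot be recovered from summaries
because they depend on the within-subject correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InfiniteStatisticError, InvalidSpecError

__all__ = [
    "SummaryRow",
    "StatResult",
    "shapiro_wilk_gate",
    "pooled_t_from_summary",
    "independent_t",
    "paired_t",
    "chi_square_2x2",
    "mann_whitney",
    "wilcoxon_paired",
    "rank_test",
]

ALPHA = 0.05


@dataclass(frozen=True)
class SummaryRow:
    """One printed table row: per-arm mean, SD and n for a parameter."""

    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def __post_init__(self) -> None:
        if self.sd_a < 0 or self.sd_b < 0:
            raise InvalidSpecError("SDs must be non-negative")
        if self.n_a < 2 or self.n_b < 2:
            raise InvalidSpecError("arm sizes must be at least 2")


@dataclass(frozen=True)
class StatResult:
    """One test outcome: statistic, degrees of freedom and p-value."""

    test: str
    statistic: float
    df: float | None
    p: float
    alpha: float = ALPHA
    two_tailed: bool = True
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or np.isnan(self.p)):
            raise InvalidSpecError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def shapiro_wilk_gate(sample: Sequence[float], alpha: float = ALPHA) -> str:
    """Route a sample to parametric or rank-based testing.

    Returns ``"normal"`` when the Shapiro-Wilk test does not reject
    normality at ``alpha``, else ``"skewed"``.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise InvalidSpecError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise InvalidSpecError("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(x)
    return "normal" if res.pvalue >= alpha else "skewed"


def pooled_t_from_summary(row: SummaryRow, welch: bool = False) -> StatResult:
    """Two-sample t-test recomputed from a printed mean/SD/n row.

    Default is the Student pooled-variance statistic

        t = (mA - mB) / (sp * sqrt(1/nA + 1/nB)),
        sp^2 = ((nA-1) sA^2 + (nB-1) sB^2) / (nA + nB - 2),

    with ``df = nA + nB - 2`` and a two-tailed p; ``welch=True`` uses the
    unequal-variance statistic with Welch-Satterthwaite df instead.
    """
    if row.sd_a == 0 and row.sd_b == 0:
        if row.mean_a == row.mean_b:
            df = row.n_a + row.n_b - 2
            return StatResult("student_t" if not welch else "welch_t", 0.0, df, 1.0)
        raise InfiniteStatisticError("zero pooled variance with unequal means")
    res = sps.ttest_ind_from_stats(
        row.mean_a,
        row.sd_a,
        row.n_a,
        row.mean_b,
        row.sd_b,
        row.n_b,
        equal_var=not welch,
    )
    df = float(res.df) if hasattr(res, "df") else (
        row.n_a + row.n_b - 2 if not welch else np.nan
    )
    return StatResult(
        "welch_t" if welch else "student_t",
        float(res.statistic),
        df,
        float(res.pvalue),
        notes={"parameter": row.parameter},
    )


def _moments_row(a: np.ndarray, b: np.ndarray, name: str = "") -> SummaryRow:
    return SummaryRow(
        name,
        float(np.mean(a)),
        float(np.std(a, ddof=1)),
        len(a),
        float(np.mean(b)),
        float(np.std(b, ddof=1)),
        len(b),
    )


def independent_t(
    a: Sequence[float],
    b: Sequence[float],
    variant: Literal["pooled", "welch"] = "pooled",
) -> StatResult:
    """Independent-samples t-test on raw data (pooled by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidSpecError("both arms need at least 2 observations")
    return pooled_t_from_summary(_moments_row(a, b), welch=(variant == "welch"))


def paired_t(before: Sequence[float], after: Sequence[float]) -> StatResult:
    """Paired t-test: one-sample t on the within-subject differences."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) != len(after):
        raise InvalidSpecError("paired samples must have equal lengths")
    if len(before) < 2:
        raise InvalidSpecError("paired t needs at least 2 pairs")
    d = before - after
    # a spread below float noise (relative to the data scale) means the
    # differences are a constant: t is 0 or undefined
    if np.ptp(d) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        if abs(d[0]) <= 1e-12 * max(1.0, float(np.abs(before).max())):
            return StatResult("paired_t", 0.0, len(d) - 1, 1.0)
        raise InfiniteStatisticError(
            "all paired differences identical and nonzero: t is infinite"
        )
    res = sps.ttest_rel(before, after)
    return StatResult("paired_t", float(res.statistic), float(len(d) - 1), float(res.pvalue))


def chi_square_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction by default.

    The table is ``[[a, b], [c, d]]``.  When any expected count falls below
    5, Fisher's exact two-tailed probability is computed as well and
    reported in ``notes`` with ``small_expected=True``.
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise InvalidSpecError("counts must be non-negative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise InfiniteStatisticError("chi-square undefined with a zero margin")
    chi2, p, df, expected = sps.chi2_contingency(counts, correction=yates)
    notes: dict = {}
    if np.any(expected < 5):
        _, fisher_p = sps.fisher_exact(counts.astype(int))
        notes = {"small_expected": True, "fisher_p": float(fisher_p)}
    return StatResult(
        "pearson_chi2_yates" if yates else "pearson_chi2",
        float(chi2),
        float(df),
        float(p),
        notes=notes,
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-tailed Mann-Whitney U rank-sum test.

    Uses the exact null distribution for tie-free samples of at most 25
    per arm and the tie-corrected normal approximation for larger or tied
    samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise InvalidSpecError("both arms need at least 1 observation")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and max(len(a), len(b)) <= 25) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult("mann_whitney_u", float(res.statistic), None, float(res.pvalue))


def wilcoxon_paired(before: Sequence[float], after: Sequence[float]) -> StatResult:
    """Two-tailed Wilcoxon signed-rank test on paired data."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) != len(after):
        raise InvalidSpecError("paired samples must have equal lengths")
    d = before - after
    if np.all(d == 0):
        raise InfiniteStatisticError("all paired differences are zero")
    res = sps.wilcoxon(before, after, alternative="two-sided")
    return StatResult("wilcoxon_signed_rank", float(res.statistic), None, float(res.pvalue))


def rank_test(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> StatResult:
    """Dispatch to the paired or unpaired rank test."""
    return wilcoxon_paired(a, b) if paired else mann_whitney(a, b)
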