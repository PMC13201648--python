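"""Shared statistical primitives.

Thin, validated wrappers around scipy/statsmodels routines with the exact
conventions the rest of the pipeline relies on: one-sided Fisher tests in
the enrichment direction, Benjamini-Hochberg FDR, rank tests that switch to
exact enumeration on small inputs, and a Pearson chi-square test of
independence without continuity correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TwoByTwoTable",
    "FisherResult",
    "fisher_exact_one_sided",
    "bh_fdr",
    "MannWhitneyResult",
    "mann_whitney_two_sided",
    "WilcoxonResult",
    "wilcoxon_paired_two_sided",
    "ChiSquareResult",
    "chi_square_independence",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """2x2 contingency table.

    Rows: in / out of the query set; columns: with / without the reference
    property. ``a`` counts query members carrying the property.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float


def fisher_exact_one_sided(table: TwoByTwoTable, haldane: bool = False) -> FisherResult:
    """One-sided (enrichment) Fisher exact test on a 2x2 table.

    Returns ``P(X >= a)`` under the hypergeometric null with the table's
    margins, together with the sample odds ratio ``(a*d)/(b*c)``. A table
    with ``b*c == 0`` and ``a*d > 0`` yields ``inf`` as sentinel unless
    ``haldane`` is set, in which case 0.5 is added to every cell for the
    odds ratio (the p-value is never corrected).
    """
    if not isinstance(table, TwoByTwoTable):
        table = TwoByTwoTable(*table)
    arr = table.as_array()
    p = float(sps.fisher_exact(arr, alternative="greater")[1])
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(p=min(p, 1.0), odds_ratio=odds)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float
    p: float
    method: str  # "exact" or "asymptotic"


_EXACT_RANK_N = 12  # combined-size switchover for exact rank-test enumeration


def mann_whitney_two_sided(x, y) -> MannWhitneyResult:
    """Unpaired two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample size is at most 12 and the
    data are tie-free; otherwise the normal approximation with tie
    correction. The mode used is reported in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= _EXACT_RANK_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):  # zero variance under total ties
        p = 1.0
    return MannWhitneyResult(statistic=float(res.statistic), p=min(p, 1.0), method=method)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p: float
    n_zero: int  # zero differences dropped
    method: str


def wilcoxon_paired_two_sided(before, after) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test on ``after - before``.

    Zero differences are dropped (their count is reported). With at most 12
    non-zero pairs the full sign-flip distribution of the signed-rank
    statistic is enumerated (average ranks for tied magnitudes); larger
    samples use the normal approximation. All-zero differences yield p = 1
    with a warning.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be 1-d arrays of equal length")
    if before.size == 0:
        raise ValueError("need at least one pair")
    diff = after - before
    n_zero = int(np.sum(diff == 0))
    d = diff[diff != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p set to 1", stacklevel=2)
        return WilcoxonResult(statistic=0.0, p=1.0, n_zero=n_zero, method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n = d.size
    if n <= _EXACT_RANK_N:
        # Enumerate all 2^n sign patterns of the signed-rank sum.
        total = 0
        extreme = 0
        mean_w = ranks.sum() / 2.0
        obs_dev = abs(w_pos - mean_w)
        for signs in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            total += 1
            if abs(w - mean_w) >= obs_dev - 1e-12:
                extreme += 1
        return WilcoxonResult(
            statistic=w_pos, p=extreme / total, n_zero=n_zero, method="exact"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.wilcoxon(d, alternative="two-sided", method="approx")
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return WilcoxonResult(statistic=w_pos, p=min(p, 1.0), n_zero=n_zero, method="asymptotic")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p: float
    dof: int


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero-margin row or column")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(statistic=float(stat), p=float(p), dof=int(dof))
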