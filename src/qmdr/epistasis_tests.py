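"""Explicit test of epistasis and added-variance comparison.

The two-locus genotype of a pair is Cartesian-coded 0-8 (``3*g1 + g2``)
and enters an OLS regression as a categorical factor; the overall
F-statistic of that regression is the epistasis test statistic.  The
explicit permutation scheme shuffles each SNP's genotype column
independently within trait-quantile strata, preserving each SNP's
marginal association while randomizing joint genotype combinations.

The variance comparison fits nested OLS models — main effects only vs
main effects plus Cartesian-coded interaction factors — and reports both
adjusted R-squared values, their percent increase, and a likelihood-ratio
p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import MISSING
from .errors import DegenerateModelError

__all__ = [
    "cartesian_code",
    "interaction_f",
    "EpistasisTestResult",
    "explicit_permutation_test",
    "VarianceComparison",
    "variance_comparison",
    "percent_increase",
]

F_LARGE = 1e6  # separation guard: F beyond this is reported as +inf


def cartesian_code(g1, g2):
    """Cartesian two-locus code ``3*g1 + g2`` in {0..8}; vectorized."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if ((g1 < 0) | (g1 > 2) | (g2 < 0) | (g2 > 2)).any():
        raise ValueError("calls must be non-missing and in {0,1,2}")
    code = 3 * g1 + g2
    return int(code) if code.ndim == 0 else code


def _complete(trait, g1, g2):
    trait = np.asarray(trait, dtype=float)
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    return trait[ok], g1[ok], g2[ok]


def _anova_f(y: np.ndarray, codes: np.ndarray) -> float:
    """Overall F of trait ~ categorical(code): between/within mean squares
    over the observed code groups."""
    groups = np.unique(codes)
    k = len(groups)
    if k < 2:
        raise DegenerateModelError(f"only {k} distinct genotype codes observed")
    n = len(y)
    if n <= k:
        raise DegenerateModelError("no residual degrees of freedom")
    grand = y.mean()
    dense = np.searchsorted(groups, codes)
    cnt = np.bincount(dense, minlength=k).astype(float)
    s = np.bincount(dense, weights=y, minlength=k)
    means = s / cnt
    ss_between = (cnt * (means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_within = ss_total - ss_between
    if ss_between <= 0:
        return 0.0
    if ss_within <= 1e-12 * max(ss_total, 1.0):
        return float("inf")
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return float("inf") if f > F_LARGE else float(f)


def interaction_f(trait, g1, g2) -> float:
    """F-statistic of the 9-cell Cartesian-coded interaction regression.

    Individuals missing either call are excluded.  Returns 0 for a
    constant trait and +inf under noiseless separation.
    """
    y, a, b = _complete(trait, g1, g2)
    return _anova_f(y, cartesian_code(a, b))


@dataclass
class EpistasisTestResult:
    observed_f: float
    null_f: np.ndarray
    pvalue: float

    def __post_init__(self) -> None:
        assert 0.0 < self.pvalue <= 1.0


def _strata(y: np.ndarray, n_strata: int) -> list[np.ndarray]:
    """Rank-based trait quantile bins; small strata merged with a neighbor."""
    n = len(y)
    n_strata = max(1, min(n_strata, n // 2))
    ranks = np.argsort(np.argsort(y, kind="mergesort"), kind="mergesort")
    labels = ranks * n_strata // n
    strata = [np.flatnonzero(labels == s) for s in range(n_strata)]
    merged: list[np.ndarray] = []
    for s in strata:
        if merged and (len(s) < 2 or len(merged[-1]) < 2):
            merged[-1] = np.concatenate([merged[-1], s])
        elif len(s):
            merged.append(s)
    return merged


def explicit_permutation_test(
    trait,
    g1,
    g2,
    n_perm: int = 1000,
    n_strata: int = 10,
    seed: int = 0,
) -> EpistasisTestResult:
    """Main-effect-preserving permutation p-value for the interaction F.

    Within each trait-quantile stratum both genotype columns are shuffled
    independently, keeping per-stratum genotype frequencies (hence
    approximate marginal effects) fixed while breaking the joint genotype
    structure.  ``p = (1 + #{null F >= observed F}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y, a, b = _complete(trait, g1, g2)
    observed = _anova_f(y, cartesian_code(a, b))
    strata = _strata(y, n_strata)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    pa, pb = a.copy(), b.copy()
    for i in range(n_perm):
        for idx in strata:
            pa[idx] = a[idx][rng.permutation(len(idx))]
            pb[idx] = b[idx][rng.permutation(len(idx))]
        try:
            null[i] = _anova_f(y, cartesian_code(pa, pb))
        except DegenerateModelError:
            null[i] = np.nan
    ok = ~np.isnan(null)
    p = (1 + int((null[ok] >= observed).sum())) / (1 + int(ok.sum()))
    return EpistasisTestResult(observed_f=observed, null_f=null, pvalue=p)


# ---------------------------------------------------------------------------
# Added-variance comparison
# ---------------------------------------------------------------------------


def percent_increase(adj_r2_reduced: float, adj_r2_full: float) -> float:
    """100 * (full - reduced) / reduced."""
    return 100.0 * (adj_r2_full - adj_r2_reduced) / adj_r2_reduced


@dataclass
class VarianceComparison:
    adj_r2_reduced: float
    adj_r2_full: float
    percent_increase: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    n: int


def _fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Least-squares fit tolerant of rank deficiency; returns (RSS, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _adj_r2(rss: float, tss: float, n: int, rank: int) -> float:
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - rank)


def _interaction_dummies(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """One-hot columns for the observed Cartesian codes (first level
    dropped; redundancy with main effects is handled by rank-aware fits)."""
    codes = cartesian_code(g1, g2)
    levels = np.unique(codes)
    return (codes[:, None] == levels[None, 1:]).astype(float)


def variance_comparison(
    trait,
    index_snp_calls,
    member_snp_calls: list[np.ndarray],
    interacting_pairs: list[tuple[int, int]],
) -> VarianceComparison:
    """Nested comparison of main-effects-only vs interaction models.

    Reduced model: intercept + index SNP + all member SNPs (additive).
    Full model: reduced + one Cartesian-coded categorical factor per pair
    (pairs index into ``member_snp_calls``).  Complete cases only; rank
    deficiencies are absorbed by pseudo-inverse fits with a warning.
    """
    y = np.asarray(trait, dtype=float)
    members = [np.asarray(c) for c in member_snp_calls]
    index_col = None if index_snp_calls is None else np.asarray(index_snp_calls)
    ok = np.ones(len(y), dtype=bool)
    for c in members + ([index_col] if index_col is not None else []):
        ok &= c != MISSING
    y = y[ok]
    members = [c[ok].astype(float) for c in members]
    n = len(y)
    main_cols = ([] if index_col is None else [index_col[ok].astype(float)]) + members
    X_red = np.column_stack([np.ones(n)] + main_cols)

    inter_cols = []
    for i, j in interacting_pairs:
        inter_cols.append(_interaction_dummies(members[i], members[j]))
    X_full = np.column_stack([X_red] + inter_cols) if inter_cols else X_red

    tss = float(((y - y.mean()) ** 2).sum())
    rss_red, rank_red = _fit_ols(X_red, y)
    rss_full, rank_full = _fit_ols(X_full, y)
    if rank_full < X_full.shape[1] or rank_red < X_red.shape[1]:
        warnings.warn("collinear design columns dropped (rank-deficient fit)")

    df = rank_full - rank_red
    if df == 0 or rss_full <= 0:
        lrt_stat, lrt_p = 0.0, 1.0
    else:
        lrt_stat = n * (np.log(rss_red) - np.log(rss_full))
        lrt_p = float(stats.chi2.sf(lrt_stat, df))
    ar = _adj_r2(rss_red, tss, n, rank_red)
    af = _adj_r2(rss_full, tss, n, rank_full)
    return VarianceComparison(
        adj_r2_reduced=ar,
        adj_r2_full=af,
        percent_increase=percent_increase(ar, af) if ar != 0 else float("nan"),
        lrt_stat=float(lrt_stat),
        lrt_df=df,
        lrt_p=lrt_p,
        n=n,
    )
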