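"""Shared fixtures and independent oracles.

Oracles here deliberately avoid the package's own computation paths:
Hardy-Weinberg probabilities come from the closed-form log-factorial
expression, t-statistics from scipy, ANOVA from scipy.
"""

import numpy as np
import pytest
from scipy.special import gammaln

from qmdr.data_io import GenotypeDataset, SnpRecord


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def hwe_oracle_distribution(n: int, n_minor: int):
    """Closed-form conditional heterozygote distribution via log-factorials."""
    rare = min(n_minor, 2 * n - n_minor)
    if rare == 0:
        return np.array([0]), np.array([1.0])
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    return hets, p / p.sum()


def hwe_oracle_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    hets, probs = hwe_oracle_distribution(n, n_minor)
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def pooled_t_oracle(high, low) -> float:
    from scipy import stats

    return float(stats.ttest_ind(high, low, equal_var=True).statistic)


# ---------------------------------------------------------------------------
# Dataset helpers
# ---------------------------------------------------------------------------


def make_dataset(calls, snp_ids=None, samples=None, chrom="1") -> GenotypeDataset:
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snp_ids = snp_ids or [f"s{j+1}" for j in range(m)]
    samples = samples or [f"i{i+1}" for i in range(n)]
    snps = [SnpRecord(snp_id=s, chrom=chrom, pos=1000 * (j + 1)) for j, s in enumerate(snp_ids)]
    return GenotypeDataset(samples=samples, snps=snps, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def binomial_band(n: int, p: float, conf: float = 0.99):
    """Central binomial band for a fraction over n trials."""
    from scipy import stats

    z = stats.norm.ppf(0.5 + conf / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)
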