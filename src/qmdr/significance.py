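"""Permutation null distribution for the pair search and p-value helpers.

Each permutation shuffles the trait vector against the (untouched)
genotype matrix, re-runs the search over the same candidate pairs, and
pools the ``top_k`` best fold-mean testing statistics into one flat null
vector.  Permutations are seeded per index, so the result is independent
of execution order or worker count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GenotypeDataset
from .qmdr_engine import FoldPlan, PairSearch, QmdrModel, _all_pairs

__all__ = [
    "NullDistribution",
    "build_null",
    "empirical_pvalue",
    "raw_pvalue",
    "bonferroni",
    "significance_table",
]


@dataclass
class NullDistribution:
    """Pooled best-model statistics from permuted datasets."""

    statistics: np.ndarray
    n_perm: int
    top_k: int
    seed: int
    n_undefined: int = 0

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)
        expected = self.n_perm * self.top_k - self.n_undefined
        if len(self.statistics) != expected:
            raise ValueError(
                f"null length {len(self.statistics)} != "
                f"n_perm*top_k - undefined = {expected}"
            )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_perm: {self.n_perm}\n")
            fh.write(f"# top_k: {self.top_k}\n")
            fh.write(f"# seed: {self.seed}\n")
            fh.write(f"# n_undefined: {self.n_undefined}\n")
            fh.write("statistic\n")
            np.savetxt(fh, self.statistics, fmt="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "NullDistribution":
        meta: dict[str, int] = {}
        rows: list[float] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, val = line[1:].split(":")
                    meta[key.strip()] = int(val)
                elif line.strip() and line.strip() != "statistic":
                    rows.append(float(line))
        return cls(
            statistics=np.array(rows),
            n_perm=meta["n_perm"],
            top_k=meta["top_k"],
            seed=meta["seed"],
            n_undefined=meta.get("n_undefined", 0),
        )


def build_null(
    dataset: GenotypeDataset,
    trait: np.ndarray,
    plan: FoldPlan,
    candidate_snps: list[str] | None = None,
    candidate_pairs: list[tuple[str, str]] | None = None,
    n_perm: int = 1000,
    top_k: int = 100,
    seed: int = 0,
    empty_cell_policy: str = "low",
    search: PairSearch | None = None,
) -> NullDistribution:
    """Pool the ``top_k`` best statistics from ``n_perm`` trait shuffles.

    A pre-built :class:`PairSearch` may be passed to share the genotype
    precomputation with the observed-data search.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if search is None:
        if candidate_pairs is not None:
            pairs = sorted({(min(p), max(p)) for p in candidate_pairs})
        elif candidate_snps is not None:
            pairs = _all_pairs(candidate_snps)
        else:
            pairs = _all_pairs(dataset.snp_ids)
        search = PairSearch(dataset, pairs, plan, empty_cell_policy)
    trait = np.asarray(trait, dtype=float)
    k = min(top_k, search.n_pairs)
    pooled: list[np.ndarray] = []
    n_undefined = 0
    for i in range(n_perm):
        rng = np.random.default_rng([seed, i])
        perm = rng.permutation(trait)
        means = search.mean_test_t(perm)
        best = np.sort(means)[-k:]
        finite = best[np.isfinite(best)]
        n_undefined += k - len(finite)
        pooled.append(finite)
    return NullDistribution(
        statistics=np.concatenate(pooled),
        n_perm=n_perm,
        top_k=k,
        seed=seed,
        n_undefined=n_undefined,
    )


def raw_pvalue(observed: float, null: NullDistribution) -> float:
    """Plain proportion of null statistics >= observed (can be 0)."""
    if len(null.statistics) == 0:
        raise ValueError("empty null distribution")
    if not np.isfinite(observed):
        return 1.0 if observed < 0 else 0.0
    return float((null.statistics >= observed).mean())


def empirical_pvalue(observed: float, null: NullDistribution) -> float:
    """Add-one permutation p-value: (1 + #{null >= obs}) / (1 + len(null))."""
    if len(null.statistics) == 0:
        raise ValueError("empty null distribution")
    if not np.isfinite(observed) and observed < 0:
        return 1.0
    n_ge = int((null.statistics >= observed).sum())
    return (1 + n_ge) / (1 + len(null.statistics))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni correction: min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def significance_table(
    models: list[QmdrModel],
    null: NullDistribution,
    m: int | None = None,
) -> pd.DataFrame:
    """Per-model significance summary.

    ``m`` is the Bonferroni multiplier; defaults to the number of retained
    models (``top_k``).
    """
    if m is None:
        m = null.top_k
    rows = []
    for model in models:
        obs = model.mean_test_t
        p_add1 = empirical_pvalue(obs, null)
        rows.append(
            {
                "snp1": model.pair[0],
                "snp2": model.pair[1],
                "mean_train_t": model.mean_train_t,
                "mean_test_t": obs,
                "cvc": model.cvc,
                "raw_p": raw_pvalue(obs, null),
                "p": p_add1,
                "bonferroni_p": bonferroni(p_add1, m),
            }
        )
    return pd.DataFrame(rows)
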