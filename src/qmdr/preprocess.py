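"""Trait residualization and the main-effect SNP screen.

The quantitative trait is regressed on the supplied covariates (plus an
optional index-SNP additive code) and the residuals become the outcome for
everything downstream.  The main-effect screen is a per-SNP simple linear
regression of the residual trait on the additive genotype code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import MISSING, GenotypeDataset
from .errors import CollinearityError, InsufficientDataError

__all__ = [
    "PhenotypeTable",
    "read_phenotypes",
    "residualize_trait",
    "main_effect_scan",
    "main_effect_filter",
]


@dataclass
class PhenotypeTable:
    """Per-sample trait and covariates, keyed by sample ID.

    ``data`` is indexed by sample ID and must be complete (no missing
    values) in the trait and covariate columns; the residual column is
    populated by :func:`residualize_trait`.
    """

    data: pd.DataFrame
    trait_col: str = "trait"
    covariate_cols: tuple[str, ...] = ()
    residual_col: str | None = None

    def __post_init__(self) -> None:
        if self.trait_col not in self.data.columns:
            raise ValueError(f"missing trait column {self.trait_col!r}")
        for c in self.covariate_cols:
            if c not in self.data.columns:
                raise ValueError(f"missing covariate column {c!r}")
        used = [self.trait_col, *self.covariate_cols]
        if self.data[used].isna().any().any():
            raise ValueError("missing values in trait/covariates; complete data required")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def raw_trait(self) -> np.ndarray:
        return self.data[self.trait_col].to_numpy(dtype=float)

    @property
    def residual(self) -> np.ndarray:
        if self.residual_col is None:
            raise ValueError("trait has not been residualized")
        return self.data[self.residual_col].to_numpy(dtype=float)

    def write_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def read_phenotypes(
    path, trait_col: str = "trait", covariate_cols: tuple[str, ...] = ()
) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return PhenotypeTable(df, trait_col=trait_col, covariate_cols=tuple(covariate_cols))


def _design_matrix(
    table: PhenotypeTable,
    covariate_names: list[str],
    genotypes: GenotypeDataset | None,
    index_snp: str | None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build [1 | covariates | index genotype]; drops samples missing the
    index genotype.  Returns (X, column names, kept-sample mask)."""
    n = len(table.samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    for c in covariate_names:
        cols.append(table.data[c].to_numpy(dtype=float))
        names.append(c)
    keep = np.ones(n, dtype=bool)
    if index_snp is not None:
        if genotypes is None:
            raise ValueError("index_snp given without a genotype dataset")
        order = [genotypes.samples.index(s) for s in table.samples]
        g = genotypes.column(index_snp)[order].astype(float)
        keep = g != MISSING
        cols.append(g)
        names.append(f"snp:{index_snp}")
    X = np.column_stack(cols)[keep]
    return X, names, keep


def residualize_trait(
    table: PhenotypeTable,
    covariate_names: list[str],
    genotypes: GenotypeDataset | None = None,
    index_snp: str | None = None,
) -> PhenotypeTable:
    """OLS-residualize the raw trait on covariates (+ index-SNP code).

    Samples missing the index genotype are dropped from the returned
    table.  Raises :class:`CollinearityError` on a rank-deficient design,
    naming the dependent columns.
    """
    X, names, keep = _design_matrix(table, covariate_names, genotypes, index_snp)
    y = table.raw_trait[keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank, scanning left to right
        dependent = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                dependent.append(names[j])
            r = rj
        raise CollinearityError(f"rank-deficient design; dependent columns: {dependent}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    data = table.data.loc[keep].copy()
    data["residual"] = resid
    return replace(table, data=data, residual_col="residual")


@dataclass
class MainEffectScan:
    """Per-SNP additive-regression summary: slope, SE, two-sided p."""

    table: pd.DataFrame  # columns: snp_id, beta, se, p, n, monomorphic

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def main_effect_scan(
    genotypes: GenotypeDataset, residual_trait: np.ndarray
) -> MainEffectScan:
    """Simple linear regression of the trait on each SNP's additive code.

    Missing genotypes are excluded per SNP; monomorphic SNPs (or SNPs with
    fewer than 3 called samples) are flagged and get a missing p-value.
    Two-sided p from the slope t-statistic with n-2 df.  Vectorized over
    SNPs via masked cross-products.
    """
    y = np.asarray(residual_trait, dtype=float)
    G = genotypes.calls.astype(float)
    if len(y) != genotypes.n_samples:
        raise ValueError("trait length != sample count")
    mask = genotypes.calls != MISSING
    Gm = np.where(mask, G, 0.0)
    ym = y[:, None] * mask

    n = mask.sum(axis=0).astype(float)
    sx = Gm.sum(axis=0)
    sxx = (Gm * Gm).sum(axis=0)
    sy = ym.sum(axis=0)
    syy = (ym * y[:, None]).sum(axis=0)
    sxy = (Gm * y[:, None]).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ssx = sxx - sx * sx / n
        ssy = syy - sy * sy / n
        sxy_c = sxy - sx * sy / n
        beta = sxy_c / ssx
        alpha = sy / n - beta * sx / n
        rss = ssy - beta * sxy_c
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / ssx)
        t = beta / se
    ok = (n >= 3) & (ssx > 0)
    p = np.full(genotypes.n_snps, np.nan)
    df = n - 2
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    tbl = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "beta": np.where(ok, beta, np.nan),
            "se": np.where(ok, se, np.nan),
            "p": p,
            "n": n.astype(int),
            "monomorphic": ~ok,
        }
    )
    return MainEffectScan(tbl)


def main_effect_filter(scan: MainEffectScan, cutoff: float = 0.016) -> list[str]:
    """SNPs with p strictly below ``cutoff``, ascending-p order."""
    if scan.table.empty:
        raise InsufficientDataError("empty scan")
    t = scan.table.dropna(subset=["p"])
    t = t[t["p"] < cutoff].sort_values(["p", "snp_id"], kind="mergesort")
    return t["snp_id"].tolist()
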