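"""Seeded simulation of genotype/phenotype datasets.

Genotypes are drawn independently per SNP under Hardy-Weinberg
equilibrium at configurable minor-allele frequencies, with optional
uniform missingness and an optional LD-copy mode for QC testing.  The
quantitative trait is a sum of covariate effects (age, age squared, sex,
principal-component-like columns), additive per-SNP effects, 3x3
two-locus cell-mean interaction offsets and Gaussian noise.

:func:`make_pure_epistasis_matrix` builds interaction matrices whose
HWE-weighted marginal means are zero, i.e. planted signals with no
single-locus main effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import MISSING, GenotypeDataset, SnpRecord
from .preprocess import PhenotypeTable

__all__ = [
    "SimulationSpec",
    "PureEpistasisMatrix",
    "make_pure_epistasis_matrix",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_dataset",
]


def hwe_weights(maf: float) -> np.ndarray:
    """Genotype probabilities (P0, P1, P2) under HWE at the given MAF."""
    q, p = 1.0 - maf, maf
    return np.array([q * q, 2 * p * q, p * p])


@dataclass(frozen=True)
class PureEpistasisMatrix:
    """3x3 cell-mean offsets with zero HWE-weighted marginal means."""

    matrix: np.ndarray
    maf: float
    shift: float

    def __post_init__(self) -> None:
        w = hwe_weights(self.maf)
        assert np.abs(self.matrix @ w).max() < 1e-9
        assert np.abs(w @ self.matrix).max() < 1e-9


def make_pure_epistasis_matrix(maf: float, shift: float) -> PureEpistasisMatrix:
    """XOR-like pattern, double-centered under HWE weights, scaled so the
    HWE-weighted SD of the cell offsets equals ``shift``."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    g = np.arange(3)
    base = ((g[:, None] + g[None, :]) % 2).astype(float)  # XOR-ish checkerboard
    w = hwe_weights(maf)
    row = base @ w  # weighted row means
    col = w @ base
    grand = w @ base @ w
    centered = base - row[:, None] - col[None, :] + grand
    if shift == 0.0:
        return PureEpistasisMatrix(np.zeros((3, 3)), maf, 0.0)
    sd = np.sqrt(np.einsum("i,ij,j->", w, centered**2, w))
    if sd == 0:
        raise ValueError("degenerate pattern; cannot normalize")
    return PureEpistasisMatrix(centered * (shift / sd), maf, shift)


@dataclass
class SimulationSpec:
    """Everything needed to draw one genotype/phenotype dataset.

    ``interactions`` is a list of ``(snp_index_1, snp_index_2, 3x3 offset
    matrix)``; ``additive_betas`` maps SNP index to an additive effect.
    Covariate effects are keyed by generated covariate name (``age``,
    ``age_sq``, ``sex``, ``pc1``...).
    """

    n_samples: int = 1000
    n_snps: int = 20
    maf: float | Sequence[float] = 0.3
    missing_rate: float = 0.0
    age_range: tuple[float, float] = (20.0, 70.0)
    n_pcs: int = 3
    covariate_betas: Mapping[str, float] = field(default_factory=dict)
    additive_betas: Mapping[int, float] = field(default_factory=dict)
    interactions: list[tuple[int, int, np.ndarray]] = field(default_factory=list)
    intercept: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    ld_copies: list[tuple[int, int, float]] = field(default_factory=list)
    # ld_copies: (source index, target index, flip probability) — the target
    # SNP becomes a noisy copy of the source, for LD-pruning tests

    def __post_init__(self) -> None:
        mafs = self.maf_vector()
        if not ((mafs > 0) & (mafs <= 0.5)).all():
            raise ValueError("mafs must be in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for _, _, m in self.interactions:
            if not np.isfinite(np.asarray(m)).all():
                raise ValueError("non-finite interaction cell-mean matrix")

    def maf_vector(self) -> np.ndarray:
        if np.isscalar(self.maf):
            return np.full(self.n_snps, float(self.maf))
        maf = np.asarray(self.maf, dtype=float)
        if len(maf) != self.n_snps:
            raise ValueError("maf vector length != n_snps")
        return maf

    def covariate_names(self) -> list[str]:
        return ["age", "age_sq", "sex"] + [f"pc{i+1}" for i in range(self.n_pcs)]


def _draw_true_genotypes(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    mafs = spec.maf_vector()
    G = rng.binomial(2, mafs[None, :], size=(spec.n_samples, spec.n_snps)).astype(
        np.int8
    )
    for src, dst, flip in spec.ld_copies:
        G[:, dst] = G[:, src]
        alter = rng.random(spec.n_samples) < flip
        G[alter, dst] = rng.binomial(2, mafs[dst], size=int(alter.sum()))
    return G


def _covariates(
    spec: SimulationSpec, rng: np.random.Generator, n: int | None = None
) -> pd.DataFrame:
    n = spec.n_samples if n is None else n
    age = rng.uniform(*spec.age_range, size=n)
    data = {"age": age, "age_sq": age**2, "sex": rng.integers(0, 2, n)}
    for i in range(spec.n_pcs):
        data[f"pc{i+1}"] = rng.standard_normal(n)
    ids = [f"ind{i+1:05d}" for i in range(n)]
    return pd.DataFrame(data, index=pd.Index(ids, name="sample_id"), dtype=float)


def _trait_from(
    G: np.ndarray, cov: pd.DataFrame, spec: SimulationSpec, rng: np.random.Generator
) -> np.ndarray:
    y = np.full(spec.n_samples, spec.intercept, dtype=float)
    for name, beta in spec.covariate_betas.items():
        y += beta * cov[name].to_numpy()
    for j, beta in spec.additive_betas.items():
        y += beta * G[:, j]
    for i, j, m in spec.interactions:
        y += np.asarray(m, dtype=float)[G[:, i], G[:, j]]
    return y + rng.standard_normal(spec.n_samples) * spec.noise_sd


def _to_dataset(G: np.ndarray, cov_index: pd.Index) -> GenotypeDataset:
    snps = [
        SnpRecord(snp_id=f"snp{j+1:05d}", chrom="1", pos=1000 * (j + 1))
        for j in range(G.shape[1])
    ]
    return GenotypeDataset(samples=list(cov_index), snps=snps, calls=G)


def simulate_dataset(spec: SimulationSpec) -> tuple[GenotypeDataset, PhenotypeTable]:
    """Draw genotypes, covariates and trait in one consistent pass.

    The trait is built from the *true* genotypes; missingness is applied
    to the returned call matrix afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    G = _draw_true_genotypes(spec, rng)
    cov = _covariates(spec, rng)
    y = _trait_from(G, cov, spec, rng)
    calls = G.copy()
    if spec.missing_rate > 0:
        mask = rng.random(calls.shape) < spec.missing_rate
        calls[mask] = MISSING
    dataset = _to_dataset(calls, cov.index)
    data = cov.copy()
    data.insert(0, "trait", y)
    pheno = PhenotypeTable(
        data, trait_col="trait", covariate_cols=tuple(spec.covariate_names())
    )
    return dataset, pheno


def simulate_genotypes(spec: SimulationSpec) -> GenotypeDataset:
    """Genotypes only (HWE draws + missingness), seeded and reproducible."""
    return simulate_dataset(spec)[0]


def simulate_trait(genotypes: GenotypeDataset, spec: SimulationSpec) -> PhenotypeTable:
    """Trait built from an existing call matrix.

    Missing calls contribute their HWE expectation (2*MAF) to additive
    terms and nothing to interaction terms; prefer
    :func:`simulate_dataset` when missingness matters.
    """
    rng = np.random.default_rng(spec.seed + 1)
    cov = _covariates(spec, rng, n=genotypes.n_samples)
    G = genotypes.calls.astype(float)
    mafs = spec.maf_vector()
    y = np.full(genotypes.n_samples, spec.intercept, dtype=float)
    for name, beta in spec.covariate_betas.items():
        y += beta * cov[name].to_numpy()
    for j, beta in spec.additive_betas.items():
        g = np.where(G[:, j] == MISSING, 2 * mafs[j], G[:, j])
        y += beta * g
    for i, j, m in spec.interactions:
        both = (G[:, i] != MISSING) & (G[:, j] != MISSING)
        m = np.asarray(m, dtype=float)
        y[both] += m[G[both, i].astype(int), G[both, j].astype(int)]
    y += rng.standard_normal(genotypes.n_samples) * spec.noise_sd
    data = cov.copy()
    data.insert(0, "trait", y)
    data.index = pd.Index(genotypes.samples, name="sample_id")
    return PhenotypeTable(
        data, trait_col="trait", covariate_cols=tuple(spec.covariate_names())
    )
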