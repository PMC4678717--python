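"""Genotype input/output and quality-control filtering.

Genotypes are held as an ``n_samples x n_snps`` integer matrix of
minor-allele counts (0/1/2) with ``-1`` marking a missing call.  Readers
exist for PLINK ``.ped``/``.map``, VCF (GT field only) and a plain TSV
matrix; every reader recodes calls so that the counted allele is the
dataset-wide minor allele.

QC filters are applied in a fixed order: sample call rate, SNP call rate,
Hardy-Weinberg exact test, minor-allele frequency, LD pruning and
relatedness (pi-hat).  Each stage can be disabled by setting its threshold
to ``None``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    EmptyResultError,
    InsufficientDataError,
    ParseError,
    UndefinedValueError,
)

MISSING = -1

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeDataset",
    "QCThresholds",
    "QCReport",
    "read_genotypes",
    "write_tsv_matrix",
    "minor_allele_frequency",
    "hwe_exact_pvalue",
    "genotype_r2",
    "pi_hat",
    "apply_qc",
]


@dataclass(frozen=True)
class SnpRecord:
    """Marker metadata: identifier, chromosome, 1-based position, optional gene."""

    snp_id: str
    chrom: str = "0"
    pos: int = 0
    gene: str | None = None


@dataclass
class GenotypeDataset:
    """Sample-by-SNP matrix of minor-allele counts with metadata.

    Invariants are checked on construction: matrix shape matches the
    metadata, all non-missing calls are in {0, 1, 2}, and identifiers are
    unique.
    """

    samples: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if n != len(self.samples) or m != len(self.snps):
            raise DimensionError(
                f"calls matrix is {self.calls.shape}, expected "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(f"invalid genotype code at cell {tuple(bad)}")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample IDs")
        if len({s.snp_id for s in self.snps}) != m:
            raise ValueError("duplicate SNP IDs")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.calls[:, self.snp_index(snp_id)]

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        snp_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            samples=[self.samples[i] for i in si],
            snps=[self.snps[j] for j in mi],
            calls=self.calls[np.ix_(si, mi)],
        )


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; ``None`` disables the corresponding stage."""

    sample_call_rate_min: float | None = 0.90
    snp_call_rate_min: float | None = 0.95
    hwe_p_min: float | None = 1e-7
    maf_min: float | None = 0.05
    ld_r2_max: float | None = 0.6
    pihat_max: float | None = 0.3

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Per-stage removal counts, in application order."""

    stages: list[dict] = field(default_factory=list)
    n_samples_in: int = 0
    n_snps_in: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0

    def add(self, stage: str, axis: str, removed: int) -> None:
        self.stages.append({"stage": stage, "axis": axis, "removed": removed})

    def removed_total(self, axis: str) -> int:
        return sum(s["removed"] for s in self.stages if s["axis"] == axis)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "axis", "removed"])

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# samples: {self.n_samples_in} -> {self.n_samples_out}\n")
            fh.write(f"# snps: {self.n_snps_in} -> {self.n_snps_out}\n")
            df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str) -> GenotypeDataset:
    """Read genotypes from ``path`` in one of ``{ped_map, vcf, tsv_matrix}``.

    Calls are recoded to counts of the dataset-wide minor allele as
    estimated from the file itself.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format == "ped_map":
        return _read_ped_map(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv_matrix":
        return _read_tsv_matrix(path)
    raise ValueError(f"unknown format {format!r}")


def _read_ped_map(path: Path) -> GenotypeDataset:
    ped = path if path.suffix == ".ped" else path.with_suffix(".ped")
    map_ = ped.with_suffix(".map")
    if not ped.exists() or not map_.exists():
        raise ParseError(f"need both {ped} and {map_}")

    snps: list[SnpRecord] = []
    for lineno, line in enumerate(map_.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{map_}:{lineno}: expected 4 fields, got {len(parts)}")
        snps.append(SnpRecord(snp_id=parts[1], chrom=parts[0], pos=int(parts[3])))
    m = len(snps)

    samples: list[str] = []
    allele_rows: list[list[str]] = []
    for lineno, line in enumerate(ped.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{ped}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
            )
        samples.append(parts[1])
        allele_rows.append(parts[6:])

    n = len(samples)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        counts: dict[str, int] = {}
        for a in a1 + a2:
            if a != "0":
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            continue
        # minor allele = least frequent; ties broken by allele name so the
        # coding is deterministic
        minor = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))[0][0]
        for i in range(n):
            if a1[i] == "0" or a2[i] == "0":
                continue
            calls[i, j] = (a1[i] == minor) + (a2[i] == minor)
    return GenotypeDataset(samples=samples, snps=snps, calls=calls)


def _read_vcf(path: Path) -> GenotypeDataset:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad input
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        alt_counts = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                alt_counts[i] = sum(1 for a in alleles if a > 0)
        called = alt_counts != MISSING
        if called.any():
            alt_freq = alt_counts[called].sum() / (2 * called.sum())
            if alt_freq > 0.5:  # ALT is major: count REF instead
                alt_counts[called] = 2 - alt_counts[called]
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        snps.append(SnpRecord(snp_id=snp_id, chrom=str(var.CHROM), pos=var.POS))
        cols.append(alt_counts)
    if not cols:
        raise ParseError(f"no variant records in {path}")
    return GenotypeDataset(
        samples=samples, snps=snps, calls=np.column_stack(cols)
    )


def _read_tsv_matrix(path: Path) -> GenotypeDataset:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse TSV matrix {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"empty TSV matrix {path}")
    vals = df.to_numpy()
    calls = np.full(vals.shape, MISSING, dtype=np.int8)
    for code in ("0", "1", "2"):
        calls[vals == code] = int(code)
    unknown = (vals != vals) | np.isin(vals, ("0", "1", "2", "NA", "nan", ""))
    if not unknown.all():
        i, j = np.argwhere(~unknown)[0]
        raise ParseError(
            f"{path}: cell ({df.index[i]}, {df.columns[j]}) is not 0/1/2/NA"
        )
    # recode to minor-allele counts from the file's own frequencies
    for j in range(calls.shape[1]):
        col = calls[:, j]
        called = col != MISSING
        if called.any() and col[called].sum() / (2 * called.sum()) > 0.5:
            calls[called, j] = 2 - col[called]
    snps = [SnpRecord(snp_id=c, chrom="0", pos=j + 1) for j, c in enumerate(df.columns)]
    return GenotypeDataset(samples=list(df.index), snps=snps, calls=calls)


def write_tsv_matrix(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write the calls matrix as TSV (rows = samples, NA for missing)."""
    df = pd.DataFrame(
        dataset.calls, index=dataset.samples, columns=dataset.snp_ids
    ).astype(object)
    df[dataset.calls == MISSING] = "NA"
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Per-marker statistics
# ---------------------------------------------------------------------------


def minor_allele_frequency(column: np.ndarray) -> float:
    """Frequency of the rarer allele, excluding missing calls; in [0, 0.5]."""
    column = np.asarray(column)
    called = column != MISSING
    if not called.any():
        raise UndefinedValueError("all calls missing")
    f = column[called].sum() / (2.0 * called.sum())
    return float(min(f, 1.0 - f))


def _het_distribution(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` diploid individuals carrying ``n_minor`` copies of the minor
    allele, returns ``(het_counts, probabilities)`` over all feasible
    heterozygote counts.  Computed by the ratio recurrence seeded at the
    distribution mode for numerical stability.
    """
    rare = min(n_minor, 2 * n - n_minor)
    if rare == 0:
        return np.array([0]), np.array([1.0])
    hets = np.arange(rare % 2, rare + 1, 2)
    # mode of the distribution (approximately 2*p*q*n conditioned on parity)
    mode = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mode % 2 != rare % 2:
        mode += 1
    mode = min(max(mode, hets[0]), hets[-1])

    probs = {mode: 1.0}
    # downward: P(h-2)/P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1))
    h = mode
    while h - 2 >= hets[0]:
        hom_r = (rare - h) / 2.0
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    # upward: P(h+2)/P(h) = 4*hom_r*hom_c / ((h+2)*(h+1))
    h = mode
    while h + 2 <= hets[-1]:
        hom_r = (rare - h) / 2.0
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    p = np.array([probs[h] for h in hets])
    return hets, p / p.sum()


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact (conditional) Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote configurations — given the
    observed allele counts — whose conditional probability does not exceed
    that of the observed table (a tiny relative slack guards against
    floating-point ties).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty table")
    n_minor = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    hets, probs = _het_distribution(n, n_minor)
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def genotype_r2(col1: np.ndarray, col2: np.ndarray) -> float:
    """Squared Pearson correlation of two 0/1/2 columns, pairwise complete."""
    col1 = np.asarray(col1, dtype=float)
    col2 = np.asarray(col2, dtype=float)
    both = (col1 != MISSING) & (col2 != MISSING)
    if both.sum() < 2:
        raise InsufficientDataError("fewer than 2 pairwise-complete samples")
    x, y = col1[both], col2[both]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedValueError("column constant on shared samples")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pi_hat(
    indiv1: np.ndarray,
    indiv2: np.ndarray,
    allele_freqs: np.ndarray,
    min_shared: int = 50,
) -> float:
    """Method-of-moments IBD estimate ``P(IBD=1)/2 + P(IBD=2)``.

    PLINK-style estimator from observed identity-by-state counts and the
    per-SNP allele frequencies; clamped to [0, 1].
    """
    g1 = np.asarray(indiv1)
    g2 = np.asarray(indiv2)
    p = np.asarray(allele_freqs, dtype=float)
    shared = (g1 != MISSING) & (g2 != MISSING) & (p > 0) & (p < 1)
    if shared.sum() < min_shared:
        raise InsufficientDataError(
            f"only {int(shared.sum())} shared informative SNPs (< {min_shared})"
        )
    a, b, f = g1[shared].astype(int), g2[shared].astype(int), p[shared]
    q = 1.0 - f
    diff = np.abs(a - b)
    n0 = int((diff == 2).sum())
    n1 = int((diff == 1).sum())
    n2 = int((diff == 0).sum())

    e0_ibs0 = (2 * f**2 * q**2).sum()
    e0_ibs1 = (4 * f**3 * q + 4 * f * q**3).sum()
    e0_ibs2 = (f**4 + q**4 + 4 * f**2 * q**2).sum()
    e1_ibs1 = (2 * f**2 * q + 2 * f * q**2).sum()
    e1_ibs2 = (f**3 + q**3 + f**2 * q + f * q**2).sum()
    m = float(shared.sum())

    k0 = n0 / e0_ibs0 if e0_ibs0 > 0 else 0.0
    k1 = (n1 - k0 * e0_ibs1) / e1_ibs1 if e1_ibs1 > 0 else 0.0
    k2 = (n2 - k0 * e0_ibs2 - k1 * e1_ibs2) / m
    return float(min(1.0, max(0.0, k1 / 2.0 + k2)))


# ---------------------------------------------------------------------------
# QC driver
# ---------------------------------------------------------------------------


def _call_rates(calls: np.ndarray, axis: int) -> np.ndarray:
    return (calls != MISSING).mean(axis=axis)


def apply_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds
) -> tuple[GenotypeDataset, QCReport]:
    """Apply all enabled QC filters in order and return the survivors.

    Order: sample call rate, SNP call rate, HWE exact test, MAF, LD
    pruning (within chromosome, later SNP of each offending pair removed),
    relatedness (lower-call-rate member of each pi-hat pair removed).
    """
    if dataset.n_samples == 0 or dataset.n_snps == 0:
        raise EmptyResultError("input dataset is empty")
    report = QCReport(n_samples_in=dataset.n_samples, n_snps_in=dataset.n_snps)
    ds = dataset
    thr = thresholds

    def _check(ds: GenotypeDataset, stage: str) -> None:
        if ds.n_samples == 0:
            raise EmptyResultError(f"all samples removed at stage {stage!r}")
        if ds.n_snps == 0:
            raise EmptyResultError(f"all SNPs removed at stage {stage!r}")

    if thr.sample_call_rate_min is not None:
        keep = _call_rates(ds.calls, axis=1) >= thr.sample_call_rate_min
        report.add("sample_call_rate", "samples", int((~keep).sum()))
        ds = ds.subset(sample_idx=np.flatnonzero(keep))
        _check(ds, "sample_call_rate")

    if thr.snp_call_rate_min is not None:
        keep = _call_rates(ds.calls, axis=0) >= thr.snp_call_rate_min
        report.add("snp_call_rate", "snps", int((~keep).sum()))
        ds = ds.subset(snp_idx=np.flatnonzero(keep))
        _check(ds, "snp_call_rate")

    if thr.hwe_p_min is not None:
        keep = np.ones(ds.n_snps, dtype=bool)
        for j in range(ds.n_snps):
            col = ds.calls[:, j]
            called = col[col != MISSING]
            if called.size == 0:
                keep[j] = False
                continue
            n_aa = int((called == 2).sum())
            n_Aa = int((called == 1).sum())
            n_AA = int((called == 0).sum())
            keep[j] = hwe_exact_pvalue(n_AA, n_Aa, n_aa) >= thr.hwe_p_min
        report.add("hwe", "snps", int((~keep).sum()))
        ds = ds.subset(snp_idx=np.flatnonzero(keep))
        _check(ds, "hwe")

    if thr.maf_min is not None:
        keep = np.ones(ds.n_snps, dtype=bool)
        for j in range(ds.n_snps):
            col = ds.calls[:, j]
            if (col != MISSING).any():
                keep[j] = minor_allele_frequency(col) >= thr.maf_min
            else:
                keep[j] = False
        report.add("maf", "snps", int((~keep).sum()))
        ds = ds.subset(snp_idx=np.flatnonzero(keep))
        _check(ds, "maf")

    if thr.ld_r2_max is not None:
        keep = _ld_prune(ds, thr.ld_r2_max)
        report.add("ld_prune", "snps", int((~keep).sum()))
        ds = ds.subset(snp_idx=np.flatnonzero(keep))
        _check(ds, "ld_prune")

    if thr.pihat_max is not None:
        keep = _relatedness_filter(ds, thr.pihat_max)
        report.add("relatedness", "samples", int((~keep).sum()))
        ds = ds.subset(sample_idx=np.flatnonzero(keep))
        _check(ds, "relatedness")

    report.n_samples_out = ds.n_samples
    report.n_snps_out = ds.n_snps
    assert report.n_samples_out + report.removed_total("samples") == report.n_samples_in
    assert report.n_snps_out + report.removed_total("snps") == report.n_snps_in
    return ds, report


def _ld_prune(ds: GenotypeDataset, r2_max: float) -> np.ndarray:
    """Greedy scan in map order within each chromosome; drops the later SNP."""
    keep = np.ones(ds.n_snps, dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for j, rec in enumerate(ds.snps):
        by_chrom.setdefault(rec.chrom, []).append(j)
    for idxs in by_chrom.values():
        kept: list[int] = []
        for j in idxs:
            drop = False
            for k in kept:
                try:
                    if genotype_r2(ds.calls[:, k], ds.calls[:, j]) >= r2_max:
                        drop = True
                        break
                except (UndefinedValueError, InsufficientDataError):
                    continue
            if drop:
                keep[j] = False
            else:
                kept.append(j)
    return keep


def _relatedness_filter(ds: GenotypeDataset, pihat_max: float) -> np.ndarray:
    """Remove the lower-call-rate member of each related pair (pi-hat above
    threshold); ties broken by sample-ID order.  Skips silently when there
    are too few SNPs to estimate relatedness."""
    freqs = np.array(
        [
            minor_allele_frequency(ds.calls[:, j])
            if (ds.calls[:, j] != MISSING).any()
            else 0.0
            for j in range(ds.n_snps)
        ]
    )
    call_rate = _call_rates(ds.calls, axis=1)
    keep = np.ones(ds.n_samples, dtype=bool)
    pairs: list[tuple[str, str, int, int]] = []
    for i in range(ds.n_samples):
        for j in range(i + 1, ds.n_samples):
            try:
                ph = pi_hat(ds.calls[i], ds.calls[j], freqs)
            except InsufficientDataError:
                continue
            if ph > pihat_max:
                pairs.append((ds.samples[i], ds.samples[j], i, j))
    for _, _, i, j in sorted(pairs):
        if not (keep[i] and keep[j]):
            continue
        if call_rate[i] < call_rate[j]:
            keep[i] = False
        elif call_rate[j] < call_rate[i]:
            keep[j] = False
        else:
            keep[max(i, j, key=lambda k: ds.samples[k])] = False
    return keep
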