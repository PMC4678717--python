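"""Knowledge-based candidate filtering.

A user-supplied table lists, for each gene-gene relationship, the
knowledge sources supporting each gene's membership in it.  The
implication index of a relationship is the sum of the two genes' source
counts; relationships at or above a minimum index survive, and surviving
gene pairs are expanded to SNP-SNP candidate pairs through a SNP-to-gene
map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .data_io import GenotypeDataset

__all__ = [
    "GeneGeneModel",
    "implication_index",
    "filter_gene_models",
    "expand_to_snp_models",
    "read_knowledge_table",
    "read_snp_gene_map",
]


@dataclass(frozen=True)
class GeneGeneModel:
    """A gene pair with the knowledge sources supporting each member."""

    gene_a: str
    gene_b: str
    sources_a: frozenset[str] = frozenset()
    sources_b: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-relationship for gene {self.gene_a!r}")

    @property
    def implication_index(self) -> int:
        return len(self.sources_a) + len(self.sources_b)


def implication_index(model: GeneGeneModel) -> int:
    """Number of supporting sources summed over both genes."""
    return model.implication_index


def filter_gene_models(
    models: list[GeneGeneModel], min_index: int = 5
) -> list[GeneGeneModel]:
    """Keep models whose implication index is >= ``min_index`` (inclusive)."""
    return [m for m in models if m.implication_index >= min_index]


def read_knowledge_table(path) -> list[GeneGeneModel]:
    """Read a TSV with columns ``gene_a``, ``gene_b``, ``source``.

    Each row states that ``source`` supports ``gene_a``'s membership in the
    relationship {gene_a, gene_b}; rows for the two orientations of a pair
    are merged into one canonical model.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_a", "gene_b", "source"):
        if col not in df.columns:
            raise ValueError(f"knowledge table missing column {col!r}")
    support: dict[tuple[str, str], dict[str, set[str]]] = {}
    for ga, gb, src in df[["gene_a", "gene_b", "source"]].itertuples(index=False):
        if ga == gb:
            warnings.warn(f"skipping self-relationship for gene {ga!r}")
            continue
        key = tuple(sorted((ga, gb)))
        entry = support.setdefault(key, {key[0]: set(), key[1]: set()})
        entry[ga].add(src)
    return [
        GeneGeneModel(
            gene_a=a,
            gene_b=b,
            sources_a=frozenset(sets[a]),
            sources_b=frozenset(sets[b]),
        )
        for (a, b), sets in sorted(support.items())
    ]


def read_snp_gene_map(path, dataset: GenotypeDataset | None = None) -> dict[str, str]:
    """Read a TSV with columns ``snp_id``, ``gene`` (many SNPs to one gene).

    If ``dataset`` is given, SNPs absent from it are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("snp_id", "gene"):
        if col not in df.columns:
            raise ValueError(f"SNP-gene map missing column {col!r}")
    mapping = dict(df[["snp_id", "gene"]].itertuples(index=False))
    if dataset is not None:
        known = set(dataset.snp_ids)
        dropped = sorted(set(mapping) - known)
        if dropped:
            warnings.warn(f"{len(dropped)} mapped SNPs absent from dataset: {dropped[:5]}...")
            mapping = {s: g for s, g in mapping.items() if s in known}
    return mapping


def expand_to_snp_models(
    gene_models: list[GeneGeneModel], snp_gene_map: dict[str, str]
) -> list[tuple[str, str]]:
    """Cartesian-expand gene pairs to SNP pairs.

    Pairs are canonicalized (lexicographic order), deduplicated and
    self-pairs excluded; a gene with no mapped SNPs skips its models with
    a warning.
    """
    if not snp_gene_map:
        raise ValueError("empty SNP-gene map")
    by_gene: dict[str, list[str]] = {}
    for snp, gene in snp_gene_map.items():
        by_gene.setdefault(gene, []).append(snp)
    pairs: set[tuple[str, str]] = set()
    for model in gene_models:
        snps_a = by_gene.get(model.gene_a, [])
        snps_b = by_gene.get(model.gene_b, [])
        if not snps_a or not snps_b:
            missing = model.gene_a if not snps_a else model.gene_b
            warnings.warn(
                f"gene {missing!r} has no mapped SNPs; skipping model "
                f"({model.gene_a}, {model.gene_b})"
            )
            continue
        for sa in snps_a:
            for sb in snps_b:
                if sa != sb:
                    pairs.add((min(sa, sb), max(sa, sb)))
    return sorted(pairs)
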