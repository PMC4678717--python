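"""End-to-end orchestration: discovery and directed-replication runs.

A run executes QC, covariate residualization, candidate filtering (main
effect, knowledge-based, or both), the cross-validated pair search, the
permutation null, the significance table, and — for models passing the
corrected-p carry threshold — the explicit epistasis test and the
added-variance comparison.  All stage outputs are written as TSV under
the configured output directory together with a JSON run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, epistasis_tests, knowledge_filter, preprocess, significance
from .data_io import GenotypeDataset, QCThresholds
from .errors import ConfigError, EmptyResultError, MappingError
from .preprocess import PhenotypeTable
from .qmdr_engine import FoldPlan, PairSearch, exhaustive_search

__all__ = ["PipelineConfig", "RunManifest", "run_discovery", "run_directed"]


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str = "qmdr_out"
    # inputs (optional when data are passed in memory)
    genotype_path: str | None = None
    genotype_format: str = "tsv_matrix"
    phenotype_path: str | None = None
    trait_col: str = "trait"
    covariate_cols: tuple[str, ...] = ()
    index_snp: str | None = None
    knowledge_path: str | None = None
    snp_gene_path: str | None = None
    # stages
    qc: QCThresholds = field(default_factory=QCThresholds)
    filter_mode: str = "main_effect"  # main_effect | knowledge | both
    main_effect_cutoff: float = 0.016
    min_implication_index: int = 5
    folds: int = 10
    top_k: int = 100
    qmdr_seed: int = 0
    empty_cell_policy: str = "low"
    n_perm: int = 1000
    perm_seed: int = 0
    bonferroni_m: int | None = None  # default: top_k
    carry_threshold: float = 0.1  # corrected-p cut for the epistasis stages
    epistasis_n_perm: int = 1000
    epistasis_n_strata: int = 10
    epistasis_seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_mode not in ("main_effect", "knowledge", "both"):
            raise ConfigError(f"unknown filter_mode {self.filter_mode!r}")
        if self.filter_mode in ("knowledge", "both"):
            if self.knowledge_path is None or self.snp_gene_path is None:
                raise ConfigError(
                    "knowledge filtering requires knowledge_path and snp_gene_path"
                )
        for p in (self.genotype_path, self.phenotype_path, self.knowledge_path,
                  self.snp_gene_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")
        if isinstance(self.qc, dict):
            self.qc = QCThresholds(**self.qc)
        self.covariate_cols = tuple(self.covariate_cols)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_cols"] = list(self.covariate_cols)
        return d


@dataclass
class RunManifest:
    """Stage-by-stage record of a run: counts, seeds, timings, outputs."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    status: str = "running"
    failed_stage: str | None = None

    def log_stage(self, name: str, seconds: float, **counts) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **counts})

    def write(self, out_dir: Path) -> None:
        for f in self.outputs:
            assert (out_dir / f).exists(), f"manifest lists missing output {f}"
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


class _Stages:
    """Shared stage implementations for discovery and directed runs."""

    def __init__(
        self,
        config: PipelineConfig,
        dataset: GenotypeDataset | None,
        phenotype: PhenotypeTable | None,
    ) -> None:
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config=config.to_dict())
        self.dataset = dataset
        self.phenotype = phenotype

    def _emit(self, name: str) -> None:
        self.manifest.outputs.append(name)

    def load(self) -> None:
        t0 = time.perf_counter()
        if self.dataset is None:
            if self.cfg.genotype_path is None:
                raise ConfigError("no genotype input (file or in-memory)")
            self.dataset = data_io.read_genotypes(
                self.cfg.genotype_path, self.cfg.genotype_format
            )
        if self.phenotype is None:
            if self.cfg.phenotype_path is None:
                raise ConfigError("no phenotype input (file or in-memory)")
            self.phenotype = preprocess.read_phenotypes(
                self.cfg.phenotype_path, self.cfg.trait_col, self.cfg.covariate_cols
            )
        self.manifest.log_stage(
            "load",
            time.perf_counter() - t0,
            n_samples=self.dataset.n_samples,
            n_snps=self.dataset.n_snps,
        )

    def qc(self) -> None:
        t0 = time.perf_counter()
        self.dataset, report = data_io.apply_qc(self.dataset, self.cfg.qc)
        report.write_tsv(self.out / "qc_report.tsv")
        self._emit("qc_report.tsv")
        data_io.write_tsv_matrix(self.dataset, self.out / "genotypes_clean.tsv")
        self._emit("genotypes_clean.tsv")
        self.manifest.log_stage(
            "qc",
            time.perf_counter() - t0,
            n_samples=self.dataset.n_samples,
            n_snps=self.dataset.n_snps,
            samples_removed=report.removed_total("samples"),
            snps_removed=report.removed_total("snps"),
        )

    def align(self) -> None:
        """Intersect genotype and phenotype samples, in genotype order."""
        common = [s for s in self.dataset.samples if s in set(self.phenotype.samples)]
        if not common:
            raise EmptyResultError("no samples shared between genotypes and phenotypes")
        idx = [self.dataset.samples.index(s) for s in common]
        self.dataset = self.dataset.subset(sample_idx=idx)
        self.phenotype = preprocess.PhenotypeTable(
            self.phenotype.data.loc[common],
            trait_col=self.phenotype.trait_col,
            covariate_cols=self.phenotype.covariate_cols,
            residual_col=self.phenotype.residual_col,
        )

    def adjust(self) -> None:
        t0 = time.perf_counter()
        self.phenotype = preprocess.residualize_trait(
            self.phenotype,
            list(self.cfg.covariate_cols),
            genotypes=self.dataset,
            index_snp=self.cfg.index_snp,
        )
        # index-SNP missingness can drop samples; re-align genotypes
        keep = [self.dataset.samples.index(s) for s in self.phenotype.samples]
        self.dataset = self.dataset.subset(sample_idx=keep)
        self.phenotype.write_tsv(self.out / "phenotype_residual.tsv")
        self._emit("phenotype_residual.tsv")
        self.manifest.log_stage(
            "adjust", time.perf_counter() - t0, n_samples=self.dataset.n_samples
        )

    def filter_candidates(self) -> tuple[list[str] | None, list[tuple[str, str]] | None]:
        """Returns (candidate_snps, candidate_pairs); exactly one is set."""
        t0 = time.perf_counter()
        cfg = self.cfg
        snps: list[str] | None = None
        pairs: list[tuple[str, str]] | None = None
        if cfg.filter_mode in ("main_effect", "both"):
            scan = preprocess.main_effect_scan(self.dataset, self.phenotype.residual)
            scan.write_tsv(self.out / "main_effect_scan.tsv")
            self._emit("main_effect_scan.tsv")
            snps = preprocess.main_effect_filter(scan, cfg.main_effect_cutoff)
            if len(snps) < 2 and cfg.filter_mode == "main_effect":
                raise EmptyResultError(
                    f"main-effect filter kept {len(snps)} SNPs (< 2) "
                    f"at cutoff {cfg.main_effect_cutoff}"
                )
        if cfg.filter_mode in ("knowledge", "both"):
            models = knowledge_filter.read_knowledge_table(cfg.knowledge_path)
            kept = knowledge_filter.filter_gene_models(
                models, cfg.min_implication_index
            )
            mapping = knowledge_filter.read_snp_gene_map(
                cfg.snp_gene_path, self.dataset
            )
            kpairs = knowledge_filter.expand_to_snp_models(kept, mapping)
            if cfg.filter_mode == "knowledge":
                if not kpairs:
                    raise EmptyResultError("knowledge filter produced no SNP pairs")
                pairs = kpairs
                snps = None
            else:
                # union of both routes, expressed as explicit pairs
                import itertools

                me_pairs = (
                    {tuple(sorted(p)) for p in itertools.combinations(sorted(snps), 2)}
                    if snps
                    else set()
                )
                pairs = sorted(me_pairs | set(kpairs))
                snps = None
                if not pairs:
                    raise EmptyResultError("combined filters produced no SNP pairs")
        n_cand = len(pairs) if pairs is not None else len(snps)
        with open(self.out / "candidates.txt", "w") as fh:
            if pairs is not None:
                fh.writelines(f"{a}\t{b}\n" for a, b in pairs)
            else:
                fh.writelines(f"{s}\n" for s in snps)
        self._emit("candidates.txt")
        self.manifest.log_stage(
            "filter", time.perf_counter() - t0, mode=cfg.filter_mode, n_candidates=n_cand
        )
        return snps, pairs

    def _write_models(self, models) -> None:
        rows = []
        for m in models:
            row = {
                "snp1": m.pair[0],
                "snp2": m.pair[1],
                "mean_train_t": m.mean_train_t,
                "mean_test_t": m.mean_test_t,
                "cvc": m.cvc,
            }
            for f in range(m.n_folds):
                row[f"train_t_{f}"] = m.train_t[f]
                row[f"test_t_{f}"] = m.test_t[f]
            rows.append(row)
        pd.DataFrame(rows).to_csv(self.out / "qmdr_models.tsv", sep="\t", index=False)
        self._emit("qmdr_models.tsv")

    def search_and_test(
        self,
        candidate_snps: list[str] | None,
        candidate_pairs: list[tuple[str, str]] | None,
    ) -> pd.DataFrame:
        cfg = self.cfg
        trait = self.phenotype.residual
        plan = FoldPlan.make(self.dataset.n_samples, cfg.folds, cfg.qmdr_seed)

        t0 = time.perf_counter()
        models = exhaustive_search(
            self.dataset,
            trait,
            plan,
            candidate_snps=candidate_snps,
            candidate_pairs=candidate_pairs,
            top_k=cfg.top_k,
            empty_cell_policy=cfg.empty_cell_policy,
        )
        self._write_models(models)
        self.manifest.log_stage(
            "search", time.perf_counter() - t0, n_models_retained=len(models)
        )

        t0 = time.perf_counter()
        if candidate_pairs is not None:
            search_pairs = candidate_pairs
        else:
            search_pairs = None
        null = significance.build_null(
            self.dataset,
            trait,
            plan,
            candidate_snps=candidate_snps,
            candidate_pairs=search_pairs,
            n_perm=cfg.n_perm,
            top_k=cfg.top_k,
            seed=cfg.perm_seed,
            empty_cell_policy=cfg.empty_cell_policy,
        )
        null.write_tsv(self.out / "null_distribution.tsv")
        self._emit("null_distribution.tsv")
        table = significance.significance_table(models, null, m=cfg.bonferroni_m)
        table.to_csv(self.out / "significance.tsv", sep="\t", index=False)
        self._emit("significance.tsv")
        self.manifest.log_stage(
            "permutation",
            time.perf_counter() - t0,
            n_perm=cfg.n_perm,
            null_size=len(null.statistics),
            seed=cfg.perm_seed,
        )
        return table

    def epistasis_stage(self, table: pd.DataFrame) -> None:
        cfg = self.cfg
        t0 = time.perf_counter()
        selected = table[table["bonferroni_p"] < cfg.carry_threshold]
        rows = []
        pairs: list[tuple[str, str]] = []
        for _, r in selected.iterrows():
            g1 = self.dataset.column(r["snp1"])
            g2 = self.dataset.column(r["snp2"])
            res = epistasis_tests.explicit_permutation_test(
                self.phenotype.residual,
                g1,
                g2,
                n_perm=cfg.epistasis_n_perm,
                n_strata=cfg.epistasis_n_strata,
                seed=cfg.epistasis_seed,
            )
            rows.append(
                {
                    "snp1": r["snp1"],
                    "snp2": r["snp2"],
                    "observed_f": res.observed_f,
                    "explicit_epistasis_p": res.pvalue,
                }
            )
            pairs.append((r["snp1"], r["snp2"]))
        pd.DataFrame(
            rows, columns=["snp1", "snp2", "observed_f", "explicit_epistasis_p"]
        ).to_csv(self.out / "explicit_epistasis.tsv", sep="\t", index=False)
        self._emit("explicit_epistasis.tsv")

        members = sorted({s for p in pairs for s in p})
        if pairs:
            midx = {s: i for i, s in enumerate(members)}
            index_calls = (
                self.dataset.column(cfg.index_snp)
                if cfg.index_snp is not None
                else None
            )
            vc = epistasis_tests.variance_comparison(
                self.phenotype.residual if cfg.index_snp is None else self.phenotype.raw_trait,
                index_calls,
                [self.dataset.column(s) for s in members],
                [(midx[a], midx[b]) for a, b in pairs],
            )
            vc_row = {
                "adj_r2_reduced": vc.adj_r2_reduced,
                "adj_r2_full": vc.adj_r2_full,
                "percent_increase": vc.percent_increase,
                "lrt_stat": vc.lrt_stat,
                "lrt_df": vc.lrt_df,
                "lrt_p": vc.lrt_p,
                "n": vc.n,
            }
        else:
            vc_row = {}
        pd.DataFrame([vc_row] if vc_row else []).to_csv(
            self.out / "variance_comparison.tsv", sep="\t", index=False
        )
        self._emit("variance_comparison.tsv")
        self.manifest.log_stage(
            "epistasis", time.perf_counter() - t0, n_models_tested=len(pairs)
        )


def _finish(stages: _Stages) -> RunManifest:
    stages.manifest.status = "completed"
    stages.manifest.write(stages.out)
    return stages.manifest


def _run_guarded(stages: _Stages, steps: list[tuple[str, callable]]) -> RunManifest:
    for name, step in steps:
        try:
            step()
        except Exception:
            stages.manifest.status = "failed"
            stages.manifest.failed_stage = name
            stages.manifest.write(stages.out)
            raise
    return _finish(stages)


def run_discovery(
    config: PipelineConfig,
    dataset: GenotypeDataset | None = None,
    phenotype: PhenotypeTable | None = None,
) -> RunManifest:
    """Full discovery run; returns the manifest (also written as JSON)."""
    st = _Stages(config, dataset, phenotype)
    holder: dict = {}

    def _filter():
        holder["cands"] = st.filter_candidates()

    def _search():
        holder["table"] = st.search_and_test(*holder["cands"])

    def _epi():
        st.epistasis_stage(holder["table"])

    return _run_guarded(
        st,
        [
            ("load", st.load),
            ("qc", st.qc),
            ("align", st.align),
            ("adjust", st.adjust),
            ("filter", _filter),
            ("search", _search),
            ("epistasis", _epi),
        ],
    )


def run_directed(
    config: PipelineConfig,
    model_list: list[tuple[str, str]],
    dataset: GenotypeDataset | None = None,
    phenotype: PhenotypeTable | None = None,
) -> RunManifest:
    """Directed replication: evaluate only the listed pairs.

    Pairs whose SNPs are absent after QC are skipped and recorded; the
    permutation null is built over the same restricted pair set.
    """
    st = _Stages(config, dataset, phenotype)
    holder: dict = {}

    def _select():
        present = set(st.dataset.snp_ids)
        kept = [
            (min(a, b), max(a, b)) for a, b in model_list if a in present and b in present
        ]
        skipped = [list(p) for p in model_list if tuple(sorted(p)) not in set(kept)]
        st.manifest.log_stage(
            "directed_selection", 0.0, n_requested=len(model_list), n_kept=len(kept),
            skipped=skipped,
        )
        if not kept:
            raise MappingError(
                f"none of the {len(model_list)} requested pairs are present after QC"
            )
        holder["pairs"] = sorted(set(kept))

    def _search():
        holder["table"] = st.search_and_test(None, holder["pairs"])

    def _epi():
        st.epistasis_stage(holder["table"])

    return _run_guarded(
        st,
        [
            ("load", st.load),
            ("qc", st.qc),
            ("align", st.align),
            ("adjust", st.adjust),
            ("directed_selection", _select),
            ("search", _search),
            ("epistasis", _epi),
        ],
    )
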