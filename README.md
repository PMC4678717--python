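# qmdr

SNP–SNP interaction discovery for quantitative traits: genotype QC,
covariate residualization, main-effect and knowledge-based candidate
filtering, an exhaustive pairwise Quantitative-MDR search with 10-fold
cross-validation, pooled permutation significance, an explicit
(main-effect-preserving) test of epistasis, and an added-variance
comparison of nested interaction models. A seeded synthetic-data
generator makes every stage testable without external data.

## Method sketch

For each SNP pair the nine two-locus genotype cells are labelled *high*
when their training-fold mean trait strictly exceeds the overall
training mean, *low* otherwise. High and low individuals are pooled and
compared with a pooled-variance two-sample t-statistic, evaluated
out-of-fold under cross-validation; pairs are ranked by their fold-mean
testing statistic. Significance comes from a pooled permutation null:
each permutation shuffles the trait, re-runs the search, and contributes
its `top_k` best statistics; model p-values use the add-one rule and a
Bonferroni multiplier defaulting to `top_k`. Surviving models are tested
for non-additivity by regressing the trait on the Cartesian-coded
(`3*g1 + g2`, codes 0–8) two-locus genotype and comparing the F-statistic
against a null built by shuffling each SNP's genotypes within
trait-quantile strata.

## CLI

`qmdr` exposes one subcommand per stage plus two orchestrators:

```sh
qmdr simulate --n-samples 1000 --n-snps 50 --planted-pair 0 1 --shift 0.5 \
     --seed 1 --out fixtures/
qmdr qc --genotypes fixtures/genotypes.tsv --out-prefix out/clean
qmdr adjust --genotypes fixtures/genotypes.tsv --phenotype fixtures/phenotype.tsv \
     --covariates age,age_sq,sex,pc1,pc2,pc3 --out out/resid.tsv
qmdr search --genotypes fixtures/genotypes.tsv --phenotype out/resid.tsv \
     --top-k 100 --out out/models.tsv
qmdr run --config config.yaml          # full discovery pipeline
qmdr replicate --config config.yaml --models pairs.tsv   # directed mode
```

`qmdr run` takes a YAML config (see `PipelineConfig` for keys: input
paths, QC thresholds, filter mode `main_effect`/`knowledge`/`both`,
fold/permutation/seed settings) and writes per-stage TSVs plus a
`manifest.json` under the configured output directory. Genotype input
formats: PLINK `.ped`/`.map`, VCF (GT field), or a sample-by-SNP 0/1/2
TSV matrix; calls are recoded to dataset-wide minor-allele counts.

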