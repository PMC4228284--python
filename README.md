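# endotree

Multi-step discovery of disease endotypes from three data domains: a
gene-expression matrix, continuous clinical/demographic covariates, and
categorical disease-status indicators.

The core method proceeds in four steps:

1. **Correlation screen** — Pearson correlation of every covariate with
   every gene (pairwise-complete subjects), keeping genes whose minimum
   p-value beats a Bonferroni-corrected threshold (e.g. 0.05/81 ≈ 0.0006).
2. **Gene clustering** — complete-linkage hierarchical clustering of the
   selected genes' absolute-correlation profiles, cut into k clusters
   (default 11).
3. **Metagenes** — one PCA per gene cluster; every component explaining
   ≥ 5% of the cluster's variance becomes a subject-wise "metagene"
   score, named `A-1`, `F-2`, ...
4. **Decision tree** — greedy information-gain tree on the metagene
   scores to segregate subjects by disease label, with a minimum leaf
   size (default 14, i.e. floor of 10% of 146 labeled subjects), plus
   resubstitution, per-leaf and bootstrap (resample-through-fixed-tree)
   accuracy reporting.

Also included: comparison baselines (gene-wise pooled-variance t-tests,
single-domain clustering scans scored by Silhouette / Goodman–Kruskal
Gamma / C-index, and weighted multi-domain k-prototypes clustering with
biomarker flagging), and a synthetic-cohort generator that plants
endotype structure (covariates → expression → disease status) so every
stage is testable without any external data.

## CLI

Every stage is a subcommand; `run-all` executes the whole pipeline and
writes each intermediate artifact plus a `manifest.json`:

```bash
# synthetic cohort (expression.tsv, covariates.csv, indicators.csv, sex.csv, truth.json)
endotree simulate --seed 7 --out cohort/

# full pipeline on the simulated cohort
endotree run-all --expr cohort/expression.tsv --cov cohort/covariates.csv \
    --indicators cohort/indicators.csv --sex cohort/sex.csv --seed 7 --out run/

# or in one shot
endotree run-all --simulate --seed 7 --out run/

# individual stages
endotree preprocess --expr cohort/expression.tsv --cov cohort/covariates.csv \
    --sex cohort/sex.csv --iqr-threshold 2000 --out prep/
endotree correlate --expr prep/expression_log2.tsv --cov cohort/covariates.csv --out corr/
endotree cluster-genes --correlations corr/correlation_r.tsv \
    --selected corr/selected_genes.tsv --k 11 --out clusters.tsv
endotree metagenes --expr prep/expression_log2.tsv --clusters clusters.tsv --out mg/
endotree fit-tree --metagenes mg/metagene_scores.tsv --labels labels.csv \
    --min-leaf 14 --bootstrap 10000 --seed 17 --out tree/
endotree baselines ttest|scan|modk ...
```

File formats are plain text: expression as a tab-delimited genes x
subjects matrix (first column `gene_id`), covariates and indicators as
CSV keyed by `subject_id` (covariate categories/units travel in a
`*.meta.csv` sidecar). Exit codes: 0 success, 2 validation error, 3
computation error.

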