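# transgi

Identify genes whose expression affects distant DNA methylation, using
multi-SNP genetic instruments as causal anchors.

The package implements, end to end and against synthetic cohorts with known
ground truth:

- **`transgi.sim`** — a synthetic-cohort generator: LD-blocked biallelic
  dosages (latent-Gaussian, thresholded at Hardy–Weinberg quantiles, with the
  block's *dosage* correlation calibrated numerically), cis-genetic expression
  architecture with exact realized heritability, trans effects of regulator
  expression on methylation, covariate/cell-composition structure, and three
  injectable confounding scenarios (shared cis-eQTL, direct SNP→CpG,
  unmeasured cell-composition confounder). Truth tables are emitted separately
  so pipeline stages cannot see them.
- **`transgi.instruments`** — per-gene genetic instruments: stratified
  train/test split, cis-SNP selection (gene body ± 100 kb), two-step LASSO
  (cross-validation-minimum selection, then a one-standard-error refit
  constrained to keep ≥ 1 SNP; covariates unpenalized via exact
  Frisch–Waugh–Lovell partialling), and test-set validation (ANOVA
  F-statistic, partial R², strict F > 10 gate).
- **`transgi.scan`** — the directed genome-wide trans scan (> 10 Mb or
  another chromosome), OLS with covariates, and bias/inflation correction of
  the pooled z ensemble via a three-component Gaussian-mixture EM
  (null component N(bias, inflation²)); Bonferroni thresholding.
- **`transgi.specificity`** — the LD/pleiotropy cascade: neighbor-GI
  (< 1 Mb) conditioning with r > 0.95 exclusion and 0.95 greedy pruning,
  residual-pleiotropy filtering (F > 5 on neighbor expression with shared
  gene-level targets), long-range same-chromosome joint models, and
  WBC-variant correction; cumulative stage flags and accounting.
- **`transgi.characterize`** — direction-of-effect binomial skew (BH-FDR),
  region collapsing (< 1 kb) with co-localization fractions, generic Fisher
  enrichment, GC-matched background sampling, TF binding-site enrichment with
  Simes-per-TF / BH-across-TFs control, chromatin-state annotation, and cis
  (< 250 kb) expression links near target CpGs.
- **`transgi.power`** — analytic noncentral-F power for the
  instrument-to-CpG test, for both the uncorrected and the
  neighbor-corrected (partial R²) analysis, validated against Monte-Carlo
  simulation.
- **`transgi.pipeline` / `transgi.cli`** — orchestration (CPM ≥ 1 filter,
  within-cohort rank-based inverse-normal transform, principal components,
  stage sequence, TSV outputs, byte-reproducible runs) and a `click` CLI.

## CLI

```sh
# generate a synthetic cohort from a YAML config
transgi simulate --config sim.yaml --out data/

# run everything: filter -> rank-INT -> PCs -> split -> instruments ->
# scan -> calibration -> cascade -> characterization -> power
transgi run-all --data data/ --out results/ --config pipeline.yaml

# individual stages / utilities
transgi split --data data/ --out split.tsv --ratio 0.3333 --seed 1
transgi power --summary results/instrument_summary.tsv --n 4000 --out power.tsv
```

`sim.yaml` is a serialized `transgi.sim.SimConfig` (see
`SimConfig.to_yaml`; `shared_eqtl_config()` / `cell_confounder_config()`
produce ready-made scenario configs). `pipeline.yaml` is a serialized
`transgi.pipeline.PipelineConfig`; all thresholds (cis window 100 kb, trans
distance 10 Mb, neighbor window 1 Mb, correlation cutoff 0.95, F cutoffs 10
and 5, alphas) default to the standard values. Outputs are TSVs with a
one-line `#` metadata header plus a JSON-lines run log; re-running with the
same inputs and config is byte-identical.

## Library usage

```python
from transgi.sim import shared_eqtl_config, simulate
from transgi.pipeline import PipelineConfig, run_pipeline

ds = simulate(shared_eqtl_config(n_samples=1500, seed=1))
results = run_pipeline(ds, PipelineConfig(scan_pc_source="none", n_pcs=0, seed=1),
                       "out/")
final = results["records"].query("final")
```
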