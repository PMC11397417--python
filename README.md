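# phytoscore

Multi-region quality evaluation for phytochemical measurement panels.

Given replicate-level measurements of regions × variables (e.g. 8 mineral
elements and 6 quality indicators over 12 production regions with 4 replicate
trees each), the package provides:

- **core_data** — validated measurement tables, CSV I/O with `"name (unit)"`
  headers, region-level aggregation;
- **synthetic_data** — a design-matched study generator (configurable region-mean
  ranges, within-region CVs, target correlation matrix with PSD repair,
  multiplicative-Gaussian or lognormal noise) plus `plant_ordering` for planting
  a recoverable quality gradient;
- **descriptive** — summary statistics (sample SD/SE/CV), per-replicate
  sugar–acid ratios, calibration-line fitting and inverse prediction;
- **inference** — one-way ANOVA, Duncan's new multiple range test with compact
  letter displays (studentized-range quantiles at the protection level
  `1−(1−α)^(p−1)`), Pearson correlation matrices with significance stars,
  Euclidean/Bray–Curtis distances and the Mantel permutation test;
- **multivariate** — column standardization, correlation-matrix PCA
  (eigenvalues, loadings, component-score coefficients, variance
  contributions), complete-linkage hierarchical clustering;
- **scoring** — component scores `H_k = Σ_j Z_j·w_jk`, variance-contribution
  weights, the composite score `H0` and the region ranking;
- **cli_report** — the `phytoscore` CLI, end-to-end `run` orchestration with a
  reproducibility MANIFEST, and the bundled published summary tables used for
  consistency checks.

## CLI

```bash
phytoscore simulate --seed 1 --out table.csv --truth truth.json
phytoscore describe table.csv --by region --out describe.csv
phytoscore compare table.csv --panel quality --out letters.csv
phytoscore correlate table.csv --panel minerals --out-prefix corr
phytoscore mantel table.csv --panel-a minerals --var-b total_polysaccharide \
    --permutations 999 --seed 7 --out mantel.csv
phytoscore cluster table.csv --k 3 --out-prefix clu
phytoscore pca table.csv --out-prefix pca
phytoscore score table.csv --retain fixed:3 --out-prefix score
phytoscore run --config config.yaml --out results/ --seed 7
```

`run` executes the configured stages in dependency order (describe → compare →
correlate/mantel → cluster → pca → score) and writes per-stage CSVs plus
`MANIFEST.json` (config, seed, wall times, completeness). A YAML config example:

```yaml
simulate: {}        # or: input: path/to/table.csv
seed: 7
stages: [describe, compare, correlate, mantel, cluster, pca, score]
permutations: 999
retain: fixed_k
retain_k: 3
```

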