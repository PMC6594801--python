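# connkit

ROI-level brain connectivity analysis: builds per-subject functional
(Pearson-correlation) and structural (volume-normalized streamline)
networks, computes weighted graph metrics (clustering coefficient,
characteristic path length, local/global/nodal efficiency) over a
proportional-threshold sweep, quantifies hemispheric asymmetry with the
laterality index `(X_L - X_R) / (X_L + X_R)`, and performs
permutation-based group inference (tea-drinking vs non-tea-drinking
cohorts) with Benjamini-Hochberg FDR control. A synthetic-cohort module
generates complete datasets with known planted effects so every pipeline
stage can be validated against ground truth.

## Package layout

| module | contents |
|---|---|
| `connkit.atlas` | `RegionAtlas` (labels, hemisphere, DMN flag, volume), 90-parcel default |
| `connkit.cohort` | tea-frequency composite score, group assignment, pooled t / chi-square summaries |
| `connkit.networks` | functional and structural network builders, proportional thresholding |
| `connkit.metrics` | weighted graph metrics, sparsity sweep with trapezoidal integration |
| `connkit.asymmetry` | hemisphere split and laterality indices |
| `connkit.stats` | permutation tests (exhaustive or sampled), BH-FDR, group comparison fronts |
| `connkit.synthetic` | synthetic cohorts with planted DMN / efficiency / asymmetry effects |
| `connkit.pipeline` | end-to-end orchestration from a YAML config |
| `connkit.cli` | `connkit` command-line entry point |

## CLI

```bash
# generate a synthetic cohort with a planted DMN effect
connkit simulate --out data/ --seed 1 --dmn-effect 0.3

# screen the cohort table (composite tea score -> T / NT / excluded)
connkit screen data/cohort.csv

# validate inputs, then run the full analysis
connkit validate --config config.yaml
connkit run-all  --config config.yaml
```

A minimal `config.yaml`:

```yaml
cohort_table: data/cohort.csv
timeseries_dir: data/timeseries
streamlines_dir: data/streamlines
atlas: data/atlas.csv
output_dir: out
n_perm: 10000
seed: 1
```

`run-all` writes tidy TSV reports (demographics, per-subject metrics,
asymmetry indices, all group comparisons) plus a `run_log.json` with the
config hash; identical configs reproduce identical bundles.

## Conventions

- Functional networks zero negative correlations by default
  (`negative_policy: absolute` switches to absolute values).
- Structural weights are `streamlines / (vol_i + vol_j)`.
- Proportional thresholding keeps `K = round(s * N(N-1)/2)` strongest
  edges with a deterministic (row, column) tie-break, so edge sets are
  nested across the default 31-level sweep (0.10 to 0.40, step 0.01).
- Edge length is `1/weight`; clustering uses the Onnela max-normalized
  formulation (`barrat` available); disconnected pairs contribute 0 to
  efficiencies and are excluded (and counted) in the path length.
- The functional sweep is applied per hemisphere for asymmetry;
  structural networks are analyzed unthresholded by default
  (`threshold_structural: true` to sweep both).
- Permutation p-values use the `(1 + hits) / (1 + n_perm)` convention and
  switch to exhaustive enumeration when the assignment space is small.

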