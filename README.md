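# deltaconn

Longitudinal connectome-wide association analysis in Python: from ROI
time series to Pearson correlation connectomes, connectivity change
(ΔrsFC), mass-univariate baseline-adjusted edge regression with
ROI-row-wise Benjamini–Hochberg FDR, cortical-integration models,
network-frequency and hub summaries, a percentile-sweep ROC, and
two-group (patients vs controls) contrasts — plus a synthetic cohort
generator with planted effects so every stage is testable end to end.

## What it computes

- **Connectomes** — pairwise Pearson correlation over a parcellation
  (cortical networks + subcortical ROIs); change is the arithmetic
  difference of edge values between two time points.
- **Edge-wise model** — for every edge, OLS of the follow-up symptom
  score on that edge's change, adjusting for the same edge's baseline
  value and sex (`symptoms_tp2 ~ delta + rsfc_tp1 + sex + 1`), fitted in
  one vectorized pass over stacked normal equations. Cross-sectional
  per-time-point variants are included.
- **Row-wise FDR** — BH applied independently to each ROI's row of the
  edge matrix, so each edge carries two adjusted p-values (one per
  endpoint ROI); all per-ROI counts use the row of the ROI under report.
- **Cortical integration** — per-subject mean (change in) connectivity
  of a subcortical ROI set to all cortical ROIs, its OLS association with
  symptoms, an integration ratio correlated with behavior, and a
  rank-based ROC swept over outcome percentiles (median to maximum in 5%
  steps).
- **Group contrasts** — per-edge and integration-level main-effects
  ANOVA (group + sex); the group F equals the squared dummy-coded OLS t.
- **Synthetic cohorts** — seeded generators for longitudinal and
  two-group designs with planted standardized effects, a truth record for
  recovery testing, and an optional time-series mode backed by a
  nearest-correlation (Higham) projection.

## CLI

All subcommands read a YAML config (`--config`); flags override config
keys. Example end-to-end run on a simulated cohort:

```yaml
# config.yaml
seed: 7
q: 0.05
target_rois: [subthalamic_nucleus_RH]
simulate:
  n_subjects: 200
  n_cortical: 48
  n_subcortical: 6
  planted_edges: [[0, 48, -0.25]]   # (roi_a, roi_b, standardized effect)
```

```bash
deltaconn run-all --config config.yaml --out results/demo --simulate
```

writes `edge_results.tsv` (long format: edge_id, roi_row, term, beta,
se, t, p, p_adj, significant), `network_frequency.tsv`,
`hub_scores.tsv`, `integration_model.json`, `roc_sweep.tsv` and a
`manifest.json` (config hash, seed, versions, stage timings) from which
the run is reproducible. Other subcommands: `simulate`, `assemble`
(build connectomes from per-subject T×P time-series TSVs), `cwas`,
`integrate`, `roc`, `summarize`, `group-contrast` (use
`--mode group` with a two-group cohort).

## Library

```python
import deltaconn as dc

cfg = dc.SimulationConfig(seed=1, n_subjects=690, n_cortical=48, n_subcortical=6,
                          planted_edges=((0, 48, -0.18),))
dataset, truth = dc.simulate_cohort(cfg)

results = dc.rowwise_bh(dc.fit_edge_models(dataset), q=0.05)
dc.count_significant(results, roi=48, sign="negative")

profile = dc.cortical_integration(dataset, target_rois=[48])
report = dc.fit_integration_model(profile, dataset)   # beta/se/t/p/CI, R², F
sweep = dc.roc_percentile_sweep(-profile.mean_delta, dataset.symptoms_tp2)
```

## File formats

Everything is plain text: parcellation TSV (`roi_name`, `hemisphere`,
`roi_class`, `network`; ids assigned in file order), phenotype TSV
(`subject_id`, `sex`, `symptoms_tp1`, `symptoms_tp2`, optional `group`),
per-subject T×P time-series TSVs (header = ROI names), and wide
subjects × edges TSVs with `roiA__roiB` columns plus a JSON sidecar
recording the parcellation hash and options.
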