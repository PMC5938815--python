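# adasmooth

Population-threshold adaptive kernel smoothing of disease rates, packaged as a
reproducible simulation pipeline. The smoothing parameter of the adaptive
estimator is a *population threshold* `h`: at every zone centroid a circular
kernel grows, swallowing whole zones in distance order, until it encloses at
least `h` people; the zone's rate is enclosed cases over enclosed population.
The pipeline evaluates candidate thresholds — six arbitrary values plus four
proposed automatically by univariate bandwidth selectors — on synthetic,
gamma-populated zone systems with Monte Carlo case simulation.

## Components

| module | what it does |
|---|---|
| `adasmooth.geography` | synthetic zone systems: gamma moment-matching, integer zone populations with exact stratum totals, CSV/GeoJSON I/O |
| `adasmooth.simulate` | binomial Monte Carlo case replicates, baseline rates, running-RMSE convergence, coverage/bias interval diagnostics |
| `adasmooth.selectors` | threshold proposal from the zone-population sample: median, normal-scale, two-stage direct plug-in, smoothed cross-validation (Gaussian kernel) |
| `adasmooth.adaptive` | neighbor orderings, adaptive-kernel rate surfaces, regional (state) rate aggregation, crude zone-mean reference |
| `adasmooth.diagnostics` | 1-D density-curve screening of thresholds against the moment-matched gamma, rule-based curve labeling |
| `adasmooth.evaluate` | RMSE of estimated vs baseline rates per (stratum, threshold), boxplot summaries |
| `adasmooth.cli` | `adasmooth` command: stagewise or end-to-end pipeline from a YAML config, deterministic under `base_seed`, manifest with config hash |
| `adasmooth.reference` | published Texas male age-stratified populations and heart-disease death rates used as default inputs |

## CLI

```bash
adasmooth run-all --config config.yaml --out out/ [--seed 1] [--replicates 100]
```

Stages can also be run one at a time (`generate-region`, `simulate`,
`select-thresholds`, `diagnostics`, `estimate`, `evaluate`); each reads its
prerequisites from, and writes its artifacts to, `--out`. Example config:

```yaml
region: {n_zones: 400, layout: grid}
strata:
  - {label: "35-44", true_rate_per_100k: 33.87, gamma_shape: 0.9,
     gamma_scale: 1007.5, total_population: 1722904}
arbitrary_thresholds: [50, 100, 500, 1000, 5000, 10000]
replicates: 100
base_seed: 1
interval_rule: binomial_wald_95   # or se_of_mean_95
density: {grid_step: 200}
```

Artifacts (all CSV/JSON): `region.csv`, `cases.csv`, `baseline_rates.csv`,
`interval_diagnostics.csv`, `thresholds.csv`, `density_curves.csv`,
`density_labels.csv`, `state_rates.csv`, `surfaces_rep1.csv`,
`evaluation.csv`, `manifest.json`. Reruns with the same config are
bit-identical.

## Notes on method choices

- Case counts are drawn per zone as binomials (n = zone population,
  p = rate), which is distribution-identical to simulating one uniform draw
  per person and aggregating.
- Regional ("state") aggregation of zone rates is population-weighted by
  default, which makes the `h -> 0` limit coincide exactly with the
  replicate's baseline rate; an unweighted mean-of-zone-rates option
  (`weighted=False`) reproduces the shrinking-boxplot behaviour of the crude
  reference.
- Distances are Euclidean on planar coordinates; geographic inputs must be
  pre-projected.
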