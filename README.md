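# openfield

Simulation and analysis pipeline for open-field locomotion studies of
dose-dependent hypokinesia. The package provides:

- **`openfield.core`** — trajectory domain types (50×50 cm arena, tracked
  head/center/tail points, session metadata) and a plain-CSV trajectory
  dialect with a `#`-prefixed metadata header, plus cohort manifests.
- **`openfield.simulate`** — a synthetic-cohort generator: two-state
  (immobile/mobile) semi-Markov locomotion with correlated-random-walk
  bouts, corner-biased thigmotaxis, within-session and across-round
  habituation, and an Emax/Hill × Bateman pharmacodynamic suppression of
  bout initiation and speed; a balanced batch/round lattice dosing design;
  and least-squares recovery of `emax`/`ed50` from mean dose-response
  distances.
- **`openfield.metrics`** — motor metrics: distance travelled (with the
  80 cm/s jitter filter), body-axis rotation counting, per-5-min maximum
  speed (absolute and bin-averaged), immobility and freezing segmentation
  (2 s minimum episode duration; freezing ⊆ immobility), mobile-episode
  counts, and aggregation over the 10–60 min timeframe of interest.
- **`openfield.zones`** — 5×5 grid decomposition into corner/wall/center
  zones (4/12/9 cells), occupancy fractions and dwell heatmaps.
- **`openfield.stats`** — fixed-effect one-way ANOVA with Dunnett's
  comparisons against the saline control, and two-way treatment×time ANOVA
  with Sidak-adjusted per-bin contrasts emitted as p-value heatmap tables.
- **`openfield.cli`** — stagewise command-line pipeline.

All default constants (2 s episode threshold, 0.8 m/s speed-discard cap,
10–60 min TOI, 5-min bins, calibration of the saline baseline) live in
`src/openfield/defaults.yaml` and can be overridden by a user YAML config.

## CLI

```sh
# full pipeline (simulate -> metrics -> zones -> stats) into out/
openfield --seed 1 run --out out/

# or stage by stage
openfield simulate --out traj/
openfield metrics --in traj/ --out metrics.csv --bins bins.csv
openfield zones   --in traj/ --out zones.csv --heatmap heatmaps/
openfield stats   --metrics metrics.csv --bins bins.csv --out stats/
openfield report  --in out/ --out figures/
```

A custom configuration is passed with `--config cfg.yaml`; any subset of the
default YAML blocks (`arena`, `recording`, `behavior`, `pharmacodynamics`,
`doses`, `metrics`, `toi`, `stats`, `design`, `seed`) may be overridden.

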