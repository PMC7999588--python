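# fallwatch

Home-monitoring fall-risk analysis on fully synthetic cohorts. The package
simulates monitored subjects (clinical scores, daily activity schedules, 3D
centroid trajectories, optional depth frames — all with ground truth),
extracts 15 behavioral parameters from the labeled trajectories, assigns the
reference fall-risk label from Tinetti / Timed-Up-and-Go scores, benchmarks
nine classifiers over every 1- and 2-parameter combination under
leave-one-subject-out cross-validation, and runs the per-parameter two-group
statistics (test selection, Holm correction, bootstrap confidence intervals).

## Modules

| module | role |
|---|---|
| `fallwatch.synthcohort` | cohort profiles, day simulation, depth rendering, ground truth |
| `fallwatch.extract` | step detection (vertical-centroid local maxima), sit/stand transitions, activity budgets — the 15-parameter feature table |
| `fallwatch.clinlabel` | Tinetti (< 21 → high), TUG best-of-three (≥ 13.5 s → high), high-wins resolution |
| `fallwatch.mlbench` | 120 feature combinations × 9 classifiers, LOSO folds, per-fold standardization, leaderboards, decision grids |
| `fallwatch.groupstats` | Shapiro/variance-ratio gated t vs. Wilcoxon tests, Holm adjustment, relative-difference bootstrap CIs |
| `fallwatch.cliio` / `fallwatch.cli` | file formats, config, per-stage seeding, pipeline orchestration, `fallwatch` CLI |

## CLI

Every stage is independently runnable; files are the only coupling.

```sh
fallwatch simulate --config config.yaml --seed 1 --out run/   # cohort.json, *_trajectory.csv, *_truth.json
fallwatch extract  --in run/ --out run/features.csv
fallwatch label    --cohort run/cohort.json --out run/labels.csv
fallwatch evaluate --features run/features.csv --labels run/labels.csv --out run/ --seed 1
fallwatch stats    --features run/features.csv --labels run/labels.csv --out run/ --seed 1
fallwatch run      --config config.yaml --seed 1 --out run/   # everything + report.md + manifest.json
```

The YAML config mirrors `CohortConfig` (e.g. `n_subjects: 30`,
`n_low_risk: 9`, `day_duration: 28800`, `separation_mode: separable|overlap`).
A single `--seed` is expanded into documented per-stage seeds, so identical
invocations produce byte-identical outputs.

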