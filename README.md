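# adaptrt

Synthetic-cohort evaluation of adaptive prostate SBRT planning strategies.

The package builds reproducible pelvic phantom cohorts with daily anatomical
variation (target shifts and deformation, bladder/rectum filling changes), a
parametric dose engine for a reference plan and four adaptation archetypes
(non-adaptive IGRT, two warm-start-style re-optimisations, and a full
re-optimisation), a voxel-exact DVH/metric engine, tiered dose-criterion
evaluation with a penalty score, and cohort statistics (paired t-tests,
overlap-volume/penalty correlation, overlap-based adaptation triggers). It
also ships a fixture of the published per-criterion and per-patient penalty
scores so the reduction arithmetic can be verified exactly.

## Layout

| module | role |
| --- | --- |
| `adaptrt.synthetic_cohort` | patient templates, daily scenarios, voxelised structures, margin expansion, rigid registration |
| `adaptrt.dose_model` | conformal dose archetypes, OAR carving/sparing, rigid dose transport, coverage rescaling |
| `adaptrt.dvh_metrics` | cumulative DVHs, V_xGy / D_x%, overlap volumes, point-wise DVH statistics |
| `adaptrt.criteria_penalty` | criterion table (YAML config), tiering, penalty score S, cohort penalty tables, printed-table fixture |
| `adaptrt.cohort_stats` | paired t-tests, Pearson correlation, overlap-volume trigger reports |
| `adaptrt.pipeline` / `adaptrt.cli` | end-to-end study orchestration, CSV/JSON/NRRD outputs, CLI |

## CLI

```bash
adaptrt run-all --seed 20210804 --out study_out          # full 32x5 study
adaptrt run-all --patients 4 --fractions 2 --out small   # reduced cohort
adaptrt simulate --out cohort_out                        # anatomies as NRRD
adaptrt plan --out plans_out                             # dose grids as NRRD
adaptrt evaluate --plan-dir plans_out --out metrics.csv  # criteria from NRRD
adaptrt stats --metrics-csv metrics.csv --out stats_out  # t-tests, correlations
adaptrt report --penalty-csv study_out/penalty_per_criterion.csv
adaptrt verify-table3                                    # published-table check
```

`run-all` writes `metrics.csv`, the two penalty-table panels, paired
statistics, correlations, trigger reports, mean +/- SD DVH curves, reduction
percentages and a run manifest; add `--plots` for PNG DVH figures. All verbs
accept `--seed` and `--config` (YAML, see
`src/adaptrt/data/default_config.yaml` for every knob and its default).

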