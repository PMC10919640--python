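# lifetables

Distribution-aware analysis of insect life tables.

Classical life tables summarise the development time of each life stage of a
reared cohort as a mean ± standard error at each rearing temperature.  That
pair describes the data fully only if development times are Gaussian — an
assumption real cohorts routinely violate: development-time distributions
are skewed, heavy- or light-tailed, and sometimes bimodal (two developmental
groups within one population).  When the implied Gaussian is used to build
stage-structured population models, the predicted emergence peaks can land
days away from the real ones, which matters for anyone timing pest-control
interventions from such models.

This package implements the full analysis that exposes the problem, for
entomologists and population modellers working with individual-level cohort
data:

* **Individual-level cohort I/O** (`lifetables.cohort`) — one CSV row per
  reared individual (integer per-stage durations in days, death stage), plus
  derivation of the classical day × stage occupancy (stage-frequency)
  matrix, which is computable from individual histories but not vice versa.
* **Extended life-table statistics** (`lifetables.stats`) — per stage and
  temperature, over the survivors of that stage: mean development time *D*
  and its standard error, the bridge σ_D = SE·√n, median, mode(s),
  population-moment skewness *s* = m₃/m₂^(3/2) and non-excess kurtosis
  *k* = m₄/m₂² (Gaussian: *s* = 0, *k* = 3), the Shapiro–Wilk test at
  p = 0.05, normal Q–Q points, the development rate *G* = 1/*D*, and — for
  fecundity schedules — the net reproduction rate R₀ = Σₓ lₓmₓ and mean
  generation time T_G = (1/R₀) Σₓ x·lₓmₓ.
* **Impulse-response population models** (`lifetables.impulse`) — the
  rearing experiment viewed as system identification: placing N eggs at day
  0 is the input N·δ(t), and each stage is a linear time-invariant block
  with kernel w(t) (fraction of stage survivors taking exactly t days) and
  survival fraction S.  Multi-stage models compose by discrete convolution
  of kernels and multiplication of survivals — the time-domain equivalent of
  multiplying transfer functions.  The Gaussian counterpart implied by a
  (mean, SE, n) row is built by integrating the normal density over unit day
  bins; `compare_models` quantifies the gap (peak days, peak shift, L1
  distance, supports).
* **Synthetic cohorts** (`lifetables.synthetic`) — a seeded individual-based
  generator (point / normal / gamma / Gaussian-mixture stage durations,
  per-stage Bernoulli survival, daily-census discretization) so the whole
  pipeline is exercisable without any external dataset.
* **Pipeline and CLI** (`lifetables.reports`, `lifetables.cli`) — summary
  tables, Q–Q sidecars, distribution-overlay and dynamics figures, JSON
  model dumps.

## Worked example

Simulate a cohort of 300 eggs at 26 °C whose larval stage is an equal
mixture of two developmental groups (21 d and 33 d), then run the full
report:

```python
from pathlib import Path
from lifetables import CohortConfig, StageDistributionSpec
from lifetables.reports import PipelineConfig, run_pipeline

cfg = CohortConfig(
    temperature=26.0,
    stages={
        "egg": StageDistributionSpec("normal", {"mean": 4.8, "sd": 1.1}, 0.95),
        "larva": StageDistributionSpec(
            "mixture", {"components": [(0.5, 21.0, 1.0), (0.5, 33.0, 1.0)]}, 0.9
        ),
        "pupa": StageDistributionSpec("gamma", {"shape": 40.0, "scale": 0.36}, 0.9),
    },
    n_initial=300,
    seed=42,
)
run_pipeline(PipelineConfig(out_dir=Path("report"), simulation=cfg))
```

`report/summary.csv`:

```
stage,temperature_C,mean,se,n,mode,median,kurtosis,skewness,sw_W,sw_p,normal_at_0_05
egg,26.0,5.3±0.1,0.069941,286,5,5.0,3.197778,0.161359,0.936284,9e-10,False
larva,26.0,27.0±0.4,0.370538,264,21,23.0,1.158806,0.158833,0.782891,0.0,False
pupa,26.0,14.7±0.1,0.137215,241,14,15.0,3.30637,0.444984,0.964685,1.12763e-05,False
```

The larval row shows how a life table hides bimodality: the familiar
"27.0±0.4" looks unremarkable, but kurtosis 1.16 (a Gaussian would give 3)
flags the two-peaked shape, mode (21) and median (23) sit well below the
mean, and Shapiro–Wilk rejects normality outright.  The dynamics sidecar
(`report/dynamics.json`, days counted from egg laying) shows the modelling
consequence:

```
egg    empirical peak  5   gaussian peak  5   shift 0   L1 0.12
larva  empirical peak 27   gaussian peak 32   shift 5   L1 0.97
pupa   empirical peak 41   gaussian peak 47   shift 6   L1 0.59
```

The Gaussian model built from mean ± SE misses the main larval emergence
wave by 5 days — a treatment scheduled from it would target the trough
between the two real waves.

The same analyses are available from the shell:

```sh
lifetables simulate  --config cohort.yaml --out cohort.csv
lifetables summarize --input cohort.csv --all-stages --out summary.csv
lifetables impulse   --input cohort.csv --out impulse.json
lifetables compare   --input cohort.csv --table1 table1.csv --out compare.json
lifetables report    --config cohort.yaml --out-dir report/
```

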