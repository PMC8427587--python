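# stepflow

Filtering and regression analysis of high-resolution GPS + accelerometer
tracking data from ground-dwelling birds.

## The problem

Solar GPS tags on forest grouse can deliver a position fix every 5 minutes
together with short tri-axial accelerometer bursts (10 s at 20 Hz every
3 min). At this resolution the tag's positional error (meters to tens of
meters) is often *larger* than the true displacement of a slow-moving or
resting bird, so raw step lengths badly overstate movement. `stepflow`
implements a two-step analysis for such data:

1. **Classify and filter.** Fixes on the regular schedule are grouped into
   movement *bursts* (≥ 50 fixes, ≈ 4 h) and joined into *steps* with length
   `S` (m per 5 min) and turning angle `α`. Each step is labelled twice:
   *active*/*resting* from dynamic body acceleration (per-individual
   unsupervised thresholding of the smoothed ODBA series), and
   *stationary*/*transient* by a 2-state hidden Markov model with gamma step
   lengths and von Mises turning angles, decoded with the Viterbi algorithm.
   Steps classified **resting–transient** — the accelerometer says the bird
   was at rest while the GPS geometry implies a large displacement — are
   false movement caused by positional error and are excluded.
2. **Model movement traits.** On the filtered steps, movement speed `S` and
   directionality `α ∈ [0, π]` are modelled with penalized Gamma (log link)
   regressions: land-cover contrasts (reference: clear-cuts ≤ 5 y), shrinkage
   smooths (≤ 4 df) of stand structure (DBH, tree height) and wind-turbine
   covariates (visible turbines, shadow hours, distance to access roads), a
   cyclic-by-cubic tensor smooth of time of day (≤ 5 df) × day of year
   (≤ 4 df), a per-individual random intercept, and — for speed — the
   previous step length `S_{t−1}` as a linear covariate that absorbs lag-1
   residual autocorrelation.

The model for the speed response is

```
log E[S_i] = β₀ + landcover(i) + β·S_prev(i) + Σ_k f_k(x_ki)
             + te(daytime_i, julianday_i) + b_ind(i),   S_i ~ Gamma
```

with all smoothing parameters chosen by generalized cross-validation.

A first-class synthetic-data module generates ground-truth-labelled tracks
(diel activity schedules, 2-state switching movement, additive GPS error,
dropouts), accelerometer bursts, and spatially autocorrelated 25-m covariate
rasters, so every stage of the pipeline is testable without field data.

## Worked example

Simulate a small study (6 birds, 14 days, a known open-bog speed multiplier
of `exp(0.38)` injected into the movement generator) and run the full
pipeline:

```python
from stepflow import RunConfig, SimConfig
from stepflow.pipeline import simulate_to_dir, run_pipeline

cfg = SimConfig(n_individuals=6, n_days=14,
                land_cover_speed_effects={"open-bog": 0.38})
simulate_to_dir(cfg, "demo", seed=42)
res = run_pipeline("demo", RunConfig(rng_seed=42, hmm_restarts=3), "demo_out")
print(res["report"].n_per_class)
print(res["speed_fit"].summary())
```

which prints (abridged):

```
{'active-transient': 710, 'active-stationary': 1664,
 'resting-stationary': 2968, 'resting-transient': 12}

Gamma/log GAMM for step length S (m / 5 min) (n = 5342)

Predictor                         Estimate       SE        p
Intercept                            2.041    0.104    <.001
land_cover[open-bog]                 0.507    0.129    <.001
S_prev                               0.018    0.001    <.001

Smooth term                            Edf        p
s(tree_height)                        0.00    1.000
s(n_visible_turbines)                 0.00    1.000
te(daytime,julian_day)               12.11    <.001

Lag-1 residual ACF without previous-step covariate: 0.274
Lag-1 residual ACF of final model: -0.002
```

Reading the output: 12 resting–transient steps were excluded as false
movement; the injected open-bog effect (truth 0.38) is recovered at
0.507 ± 0.129; covariates generated with no effect are shrunk to ~0
effective df; and including `S_prev` removes the lag-1 residual
autocorrelation (0.274 → −0.002). The same pipeline is available from the
shell via `stepflow simulate | classify | filter | model | report | run`.

## Layout

- `stepflow.io` — Movebank-style fix CSV, accelerometer CSV, ESRI ASCII
  rasters, local transverse-Mercator projection
- `stepflow.steps`, `stepflow.activity`, `stepflow.hmm`, `stepflow.fusion` —
  the classification/filtering pipeline (`StepHMM` and
  `ActivityThresholdSegmenter` are sklearn-style estimators)
- `stepflow.covariates`, `stepflow.gam`, `stepflow.models` — covariate
  extraction and the penalized Gamma GAMMs (`GammaGAM` estimator)
- `stepflow.synthetic`, `stepflow.evaluation` — ground-truth generators and
  seeded validation experiments
- `stepflow.pipeline`, `stepflow.cli` — orchestration, manifest, CLI

See `docs/methods.md` for the statistical details and design choices.
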