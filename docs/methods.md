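# Methods

This note documents the statistical machinery in `stepflow`, the defaults it
ships with, and the design choices made where several defensible options
existed.

## Data model and geometry

A *fix* is one GPS position (individual, UTC timestamp, planar meters).
Fixes arriving as WGS84 degrees are projected with a local spherical
transverse Mercator centred on the data centroid (`stepflow.projection`);
at a study extent of ~10 km the scale distortion is far below GPS error, and
the spherical inverse is exact, so coordinate round-trips are lossless.
Timestamps are UTC everywhere; local time is presentation only.

Consecutive fixes whose gap is within `sampling_interval ± schedule_tolerance`
(default 300 ± 30 s) form a *burst*; any other gap starts a new burst, so
steps are never built across schedule interruptions. Bursts shorter than
`min_burst_fixes` (default 50 ≈ 4 h) are discarded: behavioural state
switching cannot be resolved on fragments. Fixes within
`post_capture_exclusion_days` (default 3) of capture are dropped.

A *step* joins two consecutive fixes in a burst: length `S` (Euclidean,
meters per 5-min interval, a speed proxy), heading (atan2), and turning
angle — signed in (−π, π] for the state model, absolute in [0, π] as the
directionality response. The first step of each burst has no turning angle.

## Activity classification (accelerometer)

Each 10-s burst (20 Hz, 3 axes) is reduced to one dynamic body acceleration
value: the per-axis static component is the burst mean, and DBA is the mean
over samples of the summed absolute dynamic components (the ODBA
convention). DBA is invariant to gravity and sensor bias by construction.
The 3-min DBA series is smoothed with a centered 3-sample (9-min) moving
mean — wide enough to bridge short quiet moments inside active bouts — and
split per individual into active/resting phases by the threshold minimising
the two-class within-sample variance (Otsu's criterion applied to the exact
sorted sample, not a histogram), which is deterministic and adapts to each
tag's amplitude scale. Phase boundaries sit midway between adjacent samples.

A step is *active* only if both endpoints fall inside active phases; mixed
steps count as *resting*. This deliberately errs conservative: the filter's
job is to catch false movement during rest, so borderline steps should face
the stricter test. Steps outside accelerometer coverage are labelled
`unknown` and excluded from analysis (counted separately).

## Movement-state model (HMM)

A 2-state hidden Markov model is fitted to (`S`, signed α) pooled across
individuals, each burst an independent chain realisation starting from the
stationary distribution of the transition matrix. Emissions: gamma
(parameterised by mean μ_k and sd σ_k) for step length; von Mises with mean
fixed at 0 and free concentration κ_k for the angle (standard step-HMM
practice; a nonzero mean turn has no behavioural interpretation here).
Missing angles contribute the length density only. Step lengths below 1 cm
are clamped to 1 cm to stay inside the gamma support, avoiding
zero-inflation machinery.

Fitting maximises the exact forward-algorithm likelihood numerically
(L-BFGS-B) on a working scale (log μ, log σ, log κ, logit self-transition
probabilities). The first start uses moment estimates from a median split of
the step lengths (κ started at 0.5/2.0, self-transitions at 0.9); further
restarts jitter it log-normally (sd 0.3, seeded). States are relabelled so
the *transient* state has the larger mean. The forward pass runs as a scaled
linear-space recursion vectorised across bursts (per-step densities
normalised by their cross-state maximum, forward vector renormalised every
step), and both it and the Viterbi decoder are tested against brute-force
path enumeration (|Δ log L| < 1e−8, exact path identity on bursts ≤ 10
steps). Viterbi ties break toward the stationary state.

The pooled fit (rather than per-individual) keeps the state definitions
common across birds; individual heterogeneity enters later through the
regression random intercept.

## Fusion and false-movement filtering

Activity × movement state gives four classes. *Resting–transient* steps are
excluded as false movement (large apparent displacement while the
accelerometer shows rest — GPS scatter). Excluded steps remain in the output
with `included=False` so every record stays auditable; the season crop
(month-day window 23 Apr – 8 Aug, applied per year so leap years behave) then
restricts to the common observation window. After exclusions, the previous
step length `S_prev` is recomputed: a step inherits its predecessor's `S`
only when that predecessor is included and temporally adjacent; burst
origins and steps following an exclusion receive the overall mean of
included `S` (the imputed fraction is reported).

## Penalized Gamma regressions

Both responses (speed `S`, clamped at 1 cm; absolute angle, clamped at
1e−3 rad) use a Gamma GLM with log link. The linear predictor contains:

| term | form | cap |
|---|---|---|
| land cover | treatment contrasts, reference clear-cut ≤ 5 y | — |
| `S_prev` (speed model only) | linear | — |
| DBH, tree height, visible turbines, shadow hours, road distance | shrinkage smooths | 4 df |
| daytime × Julian day | tensor: cyclic (period 24 h) × cubic shrinkage | 5 × 4 df |
| individual | ridge-penalized dummy block (i.i.d. random intercept) | — |

Flexibility caps are enforced through basis size: a smooth with `k` basis
functions has at most `k − 1` effective df after its sum-to-zero constraint,
so `k = cap + 1`. Smooths are penalized cubic B-splines on equally spaced
knots with a second-order difference penalty; *shrinkage* variants replace
the penalty's null-space eigenvalues with 0.1 × the smallest positive
eigenvalue, so a large smoothing parameter can remove a term entirely while
moderate smoothing is essentially unaffected. The cyclic basis wraps
B-splines modulo the period, making the diel curve and its derivatives
exactly periodic (continuity at 0/24 h holds to machine precision). Tensor
terms take the row-wise Kronecker product of the marginal bases with one
penalty (and one smoothing parameter) per margin and a single sum-to-zero
constraint on the block.

For the Gamma log link the IRLS weights are identically 1, so penalized
IRLS reuses one Cholesky factor of `X'X + S(λ)` per candidate λ; step
halving and convergence monitor the *penalized* deviance, which the update
minimises. Smoothing parameters — including the random-intercept ridge — are
chosen by minimising `GCV(λ) = n·D / (n − γ·edf)²` with the customary
inflation γ = 1.4, via three coordinate-descent sweeps of bounded Brent
searches over log λ. GCV was preferred over a restricted-likelihood
criterion because, with constant IRLS weights, the deviance-based score is
simple, fast and robust, and it avoids the penalty pseudo-determinant
bookkeeping that multi-λ tensor blocks require under REML; the shrinkage
behaviour the analysis relies on is preserved (validated on null
covariates).

Inference: the coefficient covariance is the Bayesian `(X'X + S)⁻¹·φ` with
φ estimated from Pearson residuals; the Gamma shape is thus treated as a
dispersion parameter rather than fixed. P-values for smooth terms are a
Wald-type approximation on the term's coefficient block with the test df
floored at 1 — deliberately rough, and not intended to replicate any
specific reference implementation's test. The random-intercept variance is
reported as φ/λ_re. Effect displays hold all other continuous covariates at
their training mean, factors at the reference level and the random intercept
at zero; extrapolation beyond the observed covariate range is flagged.

Residual lag-1 autocorrelation is the Pearson correlation of deviance
residual pairs on temporally adjacent included steps within bursts. The
speed model is fitted twice — without and with `S_prev` — so the
autocorrelation can be reported before and after the lag covariate; angles
show no residual autocorrelation, so the angle model omits it.

## Synthetic data

The generator (`stepflow.synthetic`) emulates, per individual: a 1-min
active/resting Markov chain whose target activity probability follows a
diel cosine (morning peak, logit amplitude 1.5) damped toward the summer
solstice (mimicking near-continuous daylight at high latitude), with
per-minute persistence 0.96 (mean phase length tens of minutes); during
active spells a 2-state movement chain (stationary μ = 2 m, σ = 2 m,
κ = 0.3; transient μ = 25 m, σ = 20 m, κ = 2.0; self-transitions 0.90/0.85)
emitting gamma/von Mises steps; resting intervals a small positive shuffle
displacement (0.5 m — never exactly zero, keeping the gamma support valid);
additive bivariate normal GPS error (default σ = 5 m, which puts the mean
observed step length near the 12–15 m scale typical of published grouse
tracking summaries) and independent fix dropouts (5%). Accelerometer bursts
add Gaussian dynamic noise (sd 0.8 active / 0.08 resting, in g) to a
constant gravity vector. Covariate rasters are Gaussian-filtered random
fields (25-m cells): stand variables, quantile-thresholded land-cover
classes covering all nine categories, turbine visibility as a within-radius
count on flat terrain, exponentially decaying shadow-hour surfaces, and
road polylines with a Euclidean distance transform.

A separate generator draws analysis tables directly from the regression
model (land-cover effects at published magnitudes, e.g. open-bog +0.38 on
the log scale; a seasonally damped diel cosine that is exactly flat at the
solstice; Gamma shape 0.45 matching a field CV of ~1.5; individual sd 0.1;
steps generated sequentially so `S_prev` carries genuine lag-1
autocorrelation, with the feedback covariate truncated at 60 m because a
log-linear lag with heavy-tailed noise is otherwise supercritical while real
step lengths are physically bounded).

What passing tests on these data do **not** show: robustness to non-Gaussian
or temporally correlated GPS error, tag-specific accelerometer artefacts,
terrain-dependent visibility, habitat-dependent behaviour beyond the
injected mean shifts, or the individual-by-habitat confounding that real
home ranges produce (each bird samples its own landscape; contrasts from few
individuals are accordingly uncertain, as the worked example shows).

## Validation experiment sizes

The seeded experiments in `stepflow.evaluation` use: 200 random toy bursts
(≤ 10 steps) for exactness; 20 simulations × 5,000 steps for HMM parameter
recovery; 4 individuals × 10 days with σ_GPS = 10 m for filtering precision
and activity agreement; 20 replicates × 3,000 steps for regression recovery
and shrinkage; and a 2-individual × 5-day pipeline run for record
conservation. These sizes give stable metrics while keeping the whole
battery in the low minutes on one CPU.

## Known limitations

- The activity threshold is a two-class variance split; it assumes the DBA
  series is roughly bimodal and will produce arbitrary splits on unimodal
  series (degenerate series fall back to a single resting phase).
- The HMM has exactly two states, no covariate-dependent transition
  probabilities, and is fitted pooled across individuals.
- Smoothing-parameter uncertainty is ignored in all standard errors, and
  smooth-term p-values are approximate.
- Rasters must share the working CRS and resolution; no reprojection is
  performed. GeoTIFF is not read — convert to ESRI ASCII.
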