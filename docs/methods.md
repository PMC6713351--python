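# Methods

This note records the statistical model behind `stromalight`, the design
choices made where the problem was genuinely open, the numerical machinery,
and what the synthetic-data tests do and do not establish.

## Signal model and decision flow

The mean amplitude of a depth-resolved corneal stack, averaged laterally
over the field of view at each depth, is modeled as coherent (ballistic)
light attenuated by scattering along the stroma:

* homogeneous stroma: `A(z) = A0·exp(−B z) + C`, scattering mean-free path
  `l_s = 1/B`, baseline `C` from multiply scattered photons;
* heterogeneous stroma: `A(z) = A0·exp(−z/(l_s(1+Δl_s(z)))) + C`, where
  `Δl_s(z)` is the relative deviation of the mean-free path around its bulk
  value.

The analysis runs as a gated flow. A cubic smoothing spline (generalized
cross-validation) splits the profile into smooth signal and residual noise;
the SNR — mean signal above the terminal plateau divided by the mean
absolute residual — must clear a gate (default 3.0) or the profile is
reported `insufficient_signal`. The residuals are then fitted with a
zero-mean Gaussian whose SD decays exponentially in depth,
`σ(z) = σ0·exp(−ρz) + σ_floor` (the additive floor keeps the likelihood
proper at depth where the decaying term vanishes). The mono-exponential
decay is fitted by MCMC with this `σ(z)` weighting, and its adequacy is
measured by the Birge ratio at the posterior-mean parameters with
`n_params = 3`. `b_r` below threshold (default 2.0) means homogeneous;
above it the extended model is calibrated, and the stroma is still called
homogeneous if the fitted deviation stays inside the weak band
`max |Δl_s| < 0.1`. The thresholds (3.0 / 2.0 / 0.1) are recorded in every
report and are configurable; the 0.1 band mirrors the distinction between
"statistically detectable" and "materially heterogeneous".

Transparency is summarized by `z_max/l_s` and `T = exp(−z_max/l_s)` at full
precision. For display at the conventional rounding (ratio to 2 dp, `T` on
the 10⁻³ scale), `T` is derived from the rounded ratio — the only
convention under which the displayed pairs (4.44, 11.8×10⁻³) and
(8.17, 0.28×10⁻³) are mutually consistent.

## Preprocessing

Surface detection is per lateral column: the amplitude is thresholded at a
per-column quantile (default 0.85) and the surface is the first upward
threshold crossing. A first-local-maximum variant is available, but on the
background→epithelium step the crossing detector has sub-slice bias,
whereas the supra-threshold local maximum lands a speckle grain or two deep
into the epithelium (1–3 slices of systematic bias at speckle SNR 5), which
is why the crossing mode is the default. The raw height map is median
filtered (11 px) and Savitzky–Golay smoothed (31 px, order 3) over the full
2-D lateral field by default (a per-row mode exists). Flattening shifts
each column by the rounded surface position; vacated voxels become NaN and
never enter averages. The stroma is cut from a configurable anterior offset
below the surface (default 60 µm, a typical epithelium plus Bowman's layer)
to the deepest slice with enough valid pixels; the depth origin resets to
the anterior stromal boundary, with `z[k] = k·Δz` and `z_max = n·Δz`
(half-open slice bins). Automatic layer segmentation is deliberately out of
scope — fixed offsets are reproducible and auditable.

One robustness guard sits in the spline stage: on profiles with sharp
features (scar edges) GCV can pick a near-interpolating spline that
swallows the noise. A second-difference noise estimate (trend-insensitive)
provides a floor; if the spline residuals fall far below it, the spline is
stiffened until they agree.

## Bayesian machinery

Priors are data-scaled and weakly informative: `A0` half-normal scaled to
`max(a)`, `C` half-normal scaled to the terminal plateau, `B` log-normal
centered on a log-linear regression slope, `σ0`/`σ_floor` half-normal
scaled to the residual SD, `ρ` exponential with mean one inverse profile
span. The three-parameter noise and mono-exponential posteriors are sampled
with an affine-invariant ensemble sampler (differential-evolution moves),
32 walkers × (1000 warmup + 1000 kept) by default. Convergence is gated on
split-R̂ ≤ 1.05 and bulk ESS ≥ 400 (walkers treated as chains); a gate
failure triggers up to two reruns with doubled lengths before an error is
raised. All stage seeds derive deterministically from the pipeline seed, so
a fixed configuration and input reproduce the report byte for byte.

### Extended decay model

`Δl_s(z)` is the noise-free conditional mean of a squared-exponential GP
through `n_c = 10` control values on a regular grid over `[0, z_max]`
(grid of at least 4 points enforced). Several choices here departed from
the obvious-first-attempt design, each forced by analysis:

* **Identifiability.** The likelihood constrains only the product
  `l_s·(1+Δl_s(z))`. A sum-to-zero constraint on the control values seems
  natural but selects a misleading representation: a localized scar
  (Δ=+1.5 over 30% of depth) re-expresses as Δ≈+0.4 in the scar and
  Δ≈−0.4 everywhere else, delocalizing the pathology. Instead `l_s` is
  anchored by a log-normal prior (SD 0.05) centered on the preceding
  mono-exponential fit, and every posterior draw is re-expressed exactly in
  the **median-zero gauge**: `l_s′ = l_s(1+m)`, `1+Δ′ = (1+Δ)/(1+m)` with
  `m` the draw's median control deviation. `l_s` then reads as the
  mean-free path of the unremarkable majority of the stroma and `Δl_s` as
  deviation around it, independent of anchor bias. The gauge assumes the
  pathological region is a minority of the analyzed depth; a scar covering
  half the stroma flips which region reads as "bulk" (a documented
  limitation, see below).
* **Amplitude of the correction.** The GP amplitude is set by two-stage
  empirical Bayes: a short pilot run under the base prior
  `u ~ N(0, s²K)` with `s = 0.15`, then a moments-type multiplier
  `λ = max(1, quad/(n_c s²))` (posterior-median quadratic form against its
  prior expectation), then the final gated run under `N(0, λs²K)`.
  Homogeneous profiles keep λ = 1 — strong shrinkage, chosen by null-case
  calibration so that at the design SNR the posterior-median deviation
  field stays inside the 0.1 homogeneity band — while genuine scars
  inflate λ so their amplitude is essentially prior-free (the estimate is
  self-normalizing in `s`). A sampled amplitude hyperparameter (the
  obvious alternative) creates a funnel that defeats both ensemble and
  fixed-mass Hamiltonian samplers; a marginalized heavy-tailed prior
  removes the funnel but its tails mix an order of magnitude too slowly.
* **Length scale.** Fixed at 1.25 × the control-grid spacing. With only 10
  control points a free length scale is nearly unidentified, and once the
  amplitude is marginalized its density acquires a jitter-dependent spike
  at large length scales (the control covariance becomes singular).
  Treating the resolution of the correction as a property of the grid is
  both honest and numerically sound.
* **(A0, C) marginalization.** Given `(l_s, u)` the model is linear in
  `(A0, C)`, so with normal priors they integrate out in closed form (the
  positivity truncation is ignored in the integral; posterior mass sits far
  from zero). The chain runs on `(log l_s, u)` only — 11 dimensions — and
  `(A0, C)` are drawn afterwards from their exact conditional Gaussian.
* **Sampler.** A compact Hamiltonian Monte Carlo implementation with
  analytic gradients (verified against finite differences to 10⁻⁵):
  4 independent chains, dual-averaging step size, diagonal mass seeded from
  the Hessian at the posterior mode and refined in two warmup windows
  (update ratios bounded so one sluggish window cannot collapse the mass),
  leapfrog counts drawn uniformly from 20–50, target acceptance 0.85,
  500 warmup + 1000 kept draws per chain, same R̂/ESS gates and doubling
  retries as above. The ensemble sampler was tried first and retained for
  the 3-parameter stages, but on this posterior its integrated
  autocorrelation time (~500) makes the convergence gates unattainable in
  any reasonable budget.
* **Positivity.** `1 + Δl_s(z) > 0.1` is enforced as a hard support bound;
  the fraction of draws near the bound is monitored and flagged.

### Localization

Reported heterogeneity intervals are the maximal contiguous depth ranges
whose control points are **credibly material**: the central 95% interval of
`Δl_s` lies entirely beyond the ±0.1 weak-deviation band. Requiring the
whole interval to clear the band (rather than merely exclude zero) is
deliberate: a smooth interpolator on a ~55 µm grid inevitably leaks a
small, sometimes statistically certain, deviation into the grid cell next
to a strong scar, and sub-threshold leakage is not pathology. Flagged
points are dilated by half a grid spacing and merged.

## Synthetic data

The generator is the study's test bench. Profile mode draws
`a_i = A(z_i) + ε_i` with `ε_i ~ N(0, σ(z_i))` under exactly the noise
model the pipeline assumes; a closed-form helper sets `σ0` to hit a target
SNR under the pipeline's own SNR definition. Ground-truth heterogeneity is
a smoothly tapered window of `Δl_s` (logistic edges, default taper 12–15
µm). Stack mode builds a full volume: a tilted/curved (optionally
quantized) surface, a bright epithelial band (50 µm at 2× stromal surface
amplitude), the stromal decay below it, unit-mean gamma speckle per voxel,
optional hyperreflective scar layers that multiply the ballistic term over
a depth band, and an optional per-slice common gain fluctuation. That last
component matters for realism: iid per-voxel speckle averages away as
1/√N over the field of view, so without a slice-common component a
simulated stack yields profiles with unrealistically high SNR. It defaults
to zero so that the lateral-averaging convergence invariant holds exactly.

Reference conditions used throughout the tests: the two scenario pairs
(`l_s = 108 µm, z_max = 480 µm`) and (`l_s = 69 µm, z_max = 564 µm`) at
SNR ≈ 8 with `σ(z) = σ0·e^{−z/200} + 0.2`; heterogeneity tests use
`Δl_s = +1.5` below 150 µm (taper 12 µm) at `z_max = 500 µm` with 2 µm
steps. Monte-Carlo sizes were chosen for a single-CPU test run: 30 seeds
per recovery scenario, 20 seeded runs each for the localization and
null-calibration checks, 1000 replicates for the Birge calibration; stacks
are desk-scale (32–64 px laterally) rather than instrument-scale
(1024×1024).

## What the tests show — and what they do not

Passing tests establish that the pipeline recovers its own generative
model: unbiased mean-free-path estimation at realistic SNR, a calibrated
Birge ratio under matched noise, null-calibrated deviation fields, and
correct localization of representable heterogeneity. Real corneal data
differ in ways the generator does not emulate: speckle is laterally
correlated, noise need not follow a clean exponential-plus-floor SD,
epithelium/Bowman boundaries are not sharp planes, and pathology does not
arrive as a tidy logistic window. The tests therefore validate the
machinery, not the biology.

Known limitations, found and kept on purpose:

* A hyperreflective band can only be represented by the decay-correction
  model at depths beyond `l_s·ln(gain)`; a 3× band at 50 µm depth is
  mathematically outside the model class (it would need `1+Δl_s < 0`), and
  the fit then reports a best-effort anterior deviation whose posterior can
  be hard to sample. The Birge gate still flags such profiles reliably.
* The median-zero gauge assumes pathology occupies a minority of the
  analyzed depth.
* With very low profile noise (e.g. purely iid speckle averaged over a
  large field), tiny model-mismatch residuals become "statistically
  certain" and the deviation field resolves instrument- and
  preprocessing-level artifacts, not just tissue.
* Degenerate inputs: profiles shorter than 10 points, all-zero stacks,
  offsets exceeding the stack depth, and control grids under 4 points are
  rejected with specific exceptions; flattening columns with undetected
  surfaces are excluded rather than guessed.
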