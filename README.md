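# stromalight

Quantitative corneal transparency from depth-resolved corneal image stacks.

Clinical and eye-bank assessment of corneal clarity is still largely a
subjective slit-lamp judgement. `stromalight` implements an objective,
fully quantitative alternative for any depth-resolved corneal imaging
modality (demonstrated here on full-field OCT-like amplitude stacks): it
reduces a 3-D stack to a stromal mean-amplitude depth profile, estimates
the scattering mean-free path of the stroma from the profile's exponential
attenuation, tests whether a single exponential adequately describes the
tissue, and — when it does not — localizes the departure in depth.

## The model

Within the single-scattering regime, the coherent (ballistic) component of
the backscattered amplitude follows a Lambert–Beer decay with stromal depth
*z*:

```
A(z) = A0 · exp(−B z) + C,          l_s = 1/B
```

where `A0` is the amplitude factor, `C` the baseline of multiply-scattered
photons, and `l_s` the scattering mean-free path — the central transparency
number. With the stromal thickness `z_max`, transparency is summarized by
the depth ratio `z_max / l_s` and the transmitted fraction
`T = exp(−z_max / l_s)`.

The fit is Bayesian: a cubic smoothing spline separates the random noise
component of the profile; the noise SD is itself modeled as an exponential
decay in depth, `σ(z) = σ0·exp(−ρ z) + σ_floor`, and weights the Gaussian
likelihood of the decay fit. Model adequacy is measured by the Birge ratio
(reduced weighted chi-squared) of the fit residuals,
`b_r = Σ (r_i/σ_i)² / (N − 3)`: values near 1 mean the residuals are pure
noise; values far above 1 mean the stroma is not a homogeneous exponential
attenuator. In that case an extended model is calibrated in which the
mean-free path varies with depth,

```
A(z) = A0 · exp(−z / (l_s · (1 + Δl_s(z)))) + C,
```

with `Δl_s(z)` a Gaussian-process-interpolated correction through control
points on a regular depth grid. Depth intervals where `Δl_s` is credibly
material localize the pathology; a correction that stays within the weak
band `|Δl_s| < 0.1` still counts as homogeneous.

All of this is wired into one decision flow: SNR gate → mono-exponential
fit → Birge-ratio gate → extended fit → classification
(`insufficient_signal` / `homogeneous` / `heterogeneous`) and a JSON
transparency report.

## Worked example

Simulate a healthy-cornea profile (mean-free path 108 µm, stromal
thickness 480 µm, SNR ≈ 8) and analyze it:

```bash
stromalight simulate --mode profile --ls 108 --zmax 480 --snr 8 \
    --seed 1 --out sim
stromalight run --input sim.csv --seed 2 --out report.json
```

The report printed by the second command contains (abridged):

```json
{
  "birge_ratio": 1.0541045880075024,
  "classification": "homogeneous",
  "depth_ratio": 4.57823035844031,
  "l_s": 104.84400356025863,
  "l_s_sd": 1.4237173671625096,
  "snr": 9.18493941518804,
  "transmitted_fraction": 0.010273059853833371,
  "z_max": 480.0
}
```

Reading it: the profile's signal-to-noise ratio (9.2) clears the gate; the
mono-exponential fit recovers a mean-free path of 104.8 ± 1.4 µm (truth:
108 µm) with a Birge ratio of 1.05, so the residuals are consistent with
the measured noise and the stroma is homogeneous; over the 480 µm stroma
that mean-free path corresponds to a depth ratio of 4.58 and a transmitted
coherent fraction of 10.3 × 10⁻³.

The same flow runs on a multi-page TIFF stack (surface detection,
flattening and stroma extraction happen first), or from Python:

```python
import stromalight as sl

spec = sl.sigma0_for_snr(sl.SimulationSpec(l_s=108, z_max=480, seed=1), 8.0)
profile, truth = sl.simulate_profile(spec)
report = sl.run_pipeline_on_profile(profile, sl.PipelineConfig(seed=2))
print(report.classification, report.l_s)
```

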