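# ofsca — oriented fractal scaling component analysis

Real-world 2D trajectories — centre-of-pressure (CoP) paths recorded on a
force plate during quiet standing, two-axis seismic ground acceleration,
animal movement tracks — are often *anisotropic*: they are superpositions of
long-range-correlated components with different scaling exponents pointing
along different, generally **non-orthogonal**, axes. PCA cannot recover such
axes (its axes are orthogonal by construction), and ICA fails for Gaussian
fluctuations. `ofsca` implements oriented fractal scaling component analysis,
which recovers both the orientations and the components from the
angle-dependence of a detrended scaling estimator.

## Method

Model: two independent zero-mean processes ε₁, ε₂ (e.g. fractional Gaussian
noise with Hurst exponents H₁ > H₂) mixed at angles θ₁, θ₂:

    [x⁽¹⁾; x⁽²⁾] = [[cos θ₁, cos θ₂], [sin θ₁, sin θ₂]] [ε₁; ε₂]

1. **Directional DMA.** Project the trajectory onto the axis at angle θ,
   x⁽ᶿ⁾ = x⁽¹⁾cos θ + x⁽²⁾sin θ, integrate to the profile y⁽ᶿ⁾, and compute
   the Savitzky–Golay detrended moving-average fluctuation function

       F⁽ᶿ⁾(s) = sqrt( (1/(N−s+1)) Σᵢ ( y⁽ᶿ⁾[i] − ỹ_SG^(m,s)[i] )² )

   over a log-spaced grid of odd window lengths s, for θ sweeping [0, π) in
   steps of π/64. Scales are reported as corrected scales s̃ = s/cₘ
   (c₀ = 1.00, c₂ = 1.93, c₄ = 2.74) so that DMA scale aligns with Fourier
   frequency. The log–log slope of F⁽ᶿ⁾(s̃) gives the directional scaling
   exponent α(θ).
2. **Orientation detection.** The projection at θ₁ ± 90° contains *no* ε₁
   at all (and vice versa), so α(θ) attains its minimum and maximum exactly
   orthogonal to the component axes: θ̂₁ = θ̂_min ± 90°, θ̂₂ = θ̂_max ± 90°.
3. **Decomposition.** Inverting the mixing matrix at (θ̂₁, θ̂₂) recovers
   ε̂₁, ε̂₂ in closed form; their DMA slopes and Pearson cross-correlation
   quantify the quality of the separation.

The package also ships exact simulators used to validate the estimator:
circulant-embedding fractional Gaussian noise (exact target autocovariance),
the two-component mixed-fGn model, a damped AR(2) oscillator and a pure
sinusoid (the oscillatory regimes where DMA shows a plateau beyond the
period, and where zeroth-order DMA saturates at slope 2 while fourth-order
DMA resolves the f⁻⁴ exponent α = 2.5).

## Worked example

Simulate the two-component benchmark (H₁ = 0.8 at 30°, H₂ = 0.6 at 80°,
n = 2¹⁷ samples) and decompose it:

```
$ ofsca simulate mixed --h1 0.8 --theta1 30 --h2 0.6 --theta2 80 \
        --n 131072 --seed 1 --out mixed.csv
$ ofsca analyze mixed.csv --order 2 --fit-lo 1 --fit-hi 3 --outdir out
{
  "theta_min_deg": 120.9375,
  "theta_max_deg": 171.5625,
  "theta1_deg": 30.937499999999996,
  "theta2_deg": 81.56250000000003,
  "component_alphas": [
    0.7934411891415577,
    0.5993290340905136
  ],
  "cross_corr": 0.015770442026021472
}
```

Reading: the minimum of α(θ) sits at 120.9° and the maximum at 171.6°; the
component axes, 90° away, are estimated at 30.9° and 81.6° (true: 30°/80°,
the angular grid step is π/64 ≈ 2.8°). The reconstructed components scale
with exponents 0.793 and 0.599 (true: 0.8/0.6) and are essentially
uncorrelated (r ≈ 0.016). `out/` additionally contains the directional scan
table, the α(θ) profile, both reconstructed component series and a manifest
that reproduces the run bit-for-bit.

The same `analyze` command runs on any two-column CSV/TSV (e.g. ML/AP CoP
in cm at 100 Hz — use `--fit-lo 1.2 --fit-hi 2.5` style ranges matched to
the record length, or `--order 4` for strongly non-stationary data; pass
`--path` if the columns are already an fBm-like path rather than
increments).

As a library:

```python
import numpy as np
from ofsca import mixed_fgn_spec, generate_mixed_fgn, run_ofsca

traj = generate_mixed_fgn(
    mixed_fgn_spec(0.8, np.radians(30), 0.6, np.radians(80), n=2**17, seed=1))
result = run_ofsca(traj)          # second order, 64 angles, fit 1<log10 s̃<3
print(np.degrees(result.orientation.theta1_hat),
      [f.alpha for f in result.component_fits])
```

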