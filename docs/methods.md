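# Methods

## Model and estimator

The analysis targets 2D time series {(x⁽¹⁾[i], x⁽²⁾[i])} assumed (when the
decomposition is meaningful) to be a linear mixture of two independent
zero-mean long-range-correlated components with orientations θ₁, θ₂ and
distinct scaling exponents. The directional scaling estimator is
Savitzky–Golay (SG) detrended moving-average analysis applied to the
projection at angle θ:

1. projection x⁽ᶿ⁾[i] = x⁽¹⁾[i] cos θ + x⁽²⁾[i] sin θ;
2. profile y⁽ᶿ⁾[i] = Σ_{j≤i} x⁽ᶿ⁾[j] (skipped when the input is already a
   path, CLI flag `--path`);
3. fluctuation function F⁽ᶿ⁾(s) = RMS of y⁽ᶿ⁾ minus its centred SG smooth
   of degree m and odd window s, summed over exactly the N−s+1 positions
   where the full window fits;
4. α(θ) = OLS slope of log₁₀F vs log₁₀s̃ on an *open* interval (lo, hi),
   with the corrected scale s̃ = s/cₘ, c₀ = 1.00, c₂ = 1.93, c₄ = 2.74.

The SG filter of degree m reproduces polynomials of degree ≤ m exactly, so
polynomial baseline trends of that order in the profile do not contribute
to F (verified to 1e−8 relative in the tests). Supported orders are
restricted to m ∈ {0, 2, 4}, the orders with published scale-correction
constants; the constants are hard-coded and their derivation is not
re-implemented.

Orientation detection rests on the identity x⁽ᶿ⁾ = ε₁cos(θ−θ₁) +
ε₂cos(θ−θ₂): at θ = θ₁ ± π/2 the projection is a pure rescaled copy of ε₂
(and symmetrically for ε₁), while at every other angle the forced linear
fit over a mixture reads a slope strictly between the two component
exponents. Hence θ̂_min, θ̂_max = grid argmin/argmax of α(θ), and θ̂₁, θ̂₂
are those plus π/2 wrapped mod π (adding or subtracting π/2 is the same
operation mod π). Ties in the argmin/argmax break toward the smaller angle
index. No smoothing or sub-grid interpolation of α(θ) is applied before
the argmin: the grid is the resolution. The decomposition is the exact
inverse of the mixing matrix evaluated at the estimated angles; it is
refused when |sin(θ̂₂ − θ̂₁)| < 1e−6.

## Parameters and defaults

- **Angle grid**: 64 angles, θ_k = kπ/64 (step ≈ 2.81°). Projections at θ
  and θ+π are sign flips with identical F, so [0, π) is exhaustive.
- **Scale grid**: odd integers nearest to log-spaced points, 20 per decade,
  from s = 5 (and ≥ m+2) to s ≤ N/10, deduplicated.
- **Fit range**: default 1 < log₁₀s̃ < 3 (units: samples). This is
  data-dependent in practice: shorter records or oscillatory data need a
  narrower band (the CLI exposes `--fit-lo/--fit-hi`).
- **Flatness guard**: if max α(θ) − min α(θ) < 0.02 the orientation step
  refuses with "no detectable anisotropy". The threshold is this package's
  own choice; an isotropic trajectory has no preferred axes and the
  argmin/argmax would be numerical noise. Note that a *sampled* isotropic
  trajectory can show spreads of 0.003–0.03 at n = 2¹⁶–2¹⁷, so near the
  threshold the guard is realisation-dependent by nature.
- **Benchmark length**: n = 2¹⁷ for the two-component recovery experiment,
  so the fit decade 1 < log₁₀s̃ < 3 (s up to ≈ 1930 at m = 2) retains ≥ 60
  window positions at the largest scale.

## Synthetic generators

- **fGn**: circulant (Davies–Harte) embedding of the closed-form
  autocovariance γ(k) = (σ²/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H});
  the sampled spectrum is exact, not asymptotic. Embedding eigenvalues in
  [−1e−8·max, 0) are clipped to zero; anything lower raises instead of
  silently distorting the law (for H ≥ 0.5 and the sizes used here all
  eigenvalues are non-negative; the guard exists for pathological inputs).
  Component pairs derive independent streams from one user seed by
  `SeedSequence` spawning, reduced to 31-bit integers — deterministic and
  documented.
- **Mixed fGn**: defaults mirror the benchmark conditions H₁ = 0.8 at 30°,
  H₂ = 0.6 at 80°, unit σ for both components.
- **AR(2)**: x[i] = a₁x[i−1] + a₂x[i−2] + σξ[i] with a₁ = 2r cos(2π/p),
  a₂ = −r², i.e. complex poles at radius r and resonance period p; burn-in
  of 10p samples discarded. Default r = 0.995: the narrow resonance gives
  a clean f⁻⁴ high-frequency regime. The exponent 2.5 is read *about one
  decade below the period* (order-4 fit band 0.9 < log₁₀s̃ < 1.4):
  immediately below the period the resonance peak steepens the local slope
  to ≈ 3, and at the very smallest scales it relaxes toward 2 — both
  visible in the local-slope profile and deliberately outside the fit band.
- **Sinusoid**: x[i] = A sin(2πi/p + φ). Beyond the period F(s̃) forms a
  non-increasing plateau; individual local slopes oscillate around zero
  there (interference nulls of the SG kernel against the tone), so the
  plateau is asserted on the fitted slope across the band and on the
  envelope, not pointwise.

What the generators do **not** emulate: measurement noise floors,
non-Gaussian increments, multifractality, time-varying orientations, and
the bounded/intermittent character of real CoP or seismic records. Passing
the recovery tests therefore demonstrates correctness of the estimator and
decomposition under the stated model, not that any particular real dataset
contains two pure fGn components.

## Numerical choices

- The angle scan's default path exploits linearity: the directional
  residual is r⁽ᶿ⁾ = r₁cos θ + r₂sin θ for the per-axis residuals, so
  F²(θ, s) = cos²θ⟨r₁²⟩ + sin²θ⟨r₂²⟩ + 2 sin θ cos θ⟨r₁r₂⟩ — three moments
  per scale instead of one DMA per angle. This is an exact identity, and
  the per-angle "direct" route stays available and pinned against it in
  the tests (1e−10).
- SG smoothing is FFT convolution with `scipy.signal.savgol_coeffs`;
  correctness is pinned to a per-window least-squares oracle.
- Slope fits refuse ranges containing F = 0 (log undefined) or fewer than
  two grid points; F² values driven to ~−1e−30 by rounding are clipped to
  zero before the square root.
- Local slopes are two-point finite differences between consecutive grid
  scales, attributed to log-scale midpoints.

## Experiment sizes used by the test-suite and acceptance script

Recovery experiment at full n = 2¹⁷ (11 seeds for the median checks);
white-noise limit at n = 2¹⁶; AR(2) checks at n = 2¹⁵–2¹⁶; Monte-Carlo
generator validation at 30–50 seeds. The moment-based angle scan makes a
full 64-angle, n = 2¹⁷ pipeline run take ~2 s on one CPU.

## Known limitations

- Orientation estimates are quantised to the angle grid (π/64 by default);
  no sub-grid refinement is attempted.
- Exactly two components; mixtures of three or more orientations alias
  into the two detected extrema.
- The slope fit assumes a single power-law regime inside the fit range;
  crossovers inside the range bias α(θ) toward an average slope (that bias
  is, in fact, what makes the extrema detectable, but it means α at
  non-extremal angles is not a Hurst exponent of anything).
- Records shorter than a few thousand samples leave too few windows per
  scale for a stable fit decade.
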