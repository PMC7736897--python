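"""Savitzky-Golay-filter-based detrended moving-average analysis (DMA).

The estimator compares the integrated signal (profile) with its local
Savitzky-Golay smooth over a centred window of odd length s, for a grid of
scales, and reads the Hurst-type scaling exponent alpha off the log-log
slope of the fluctuation function

    F(s) = sqrt( (1/(N-s+1)) * sum_{i=(s+1)/2}^{N-(s-1)/2}
                 ( y[i] - y_SG^(m,s)[i] )^2 ),

where y_SG^(m,s) is the degree-m SG smooth.  Because the SG filter
reproduces polynomials up to degree m exactly, the estimator is blind to
polynomial baseline trends of that order in the profile.

Higher-order detrending distorts the correspondence between the DMA window
length and Fourier frequency; published correction constants realign them:
the corrected scale is s/1.00, s/1.93 and s/2.74 for orders 0, 2 and 4.
Slope fits and plots are always expressed in corrected scales.

The per-scale smooth is computed by FFT convolution with precomputed SG
coefficients; correctness is pinned (in the test-suite) to a literal
windowed least-squares transcription, not to the implementation strategy.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

from .types import DMAConfig, FluctuationResult, Series1D, SlopeFit

__all__ = [
    "SCALE_CORRECTION",
    "corrected_scale",
    "integrate_profile",
    "sg_smooth",
    "sg_residuals",
    "fluctuation_function",
    "fit_slope",
    "local_slopes",
    "default_scales",
]

#: Scale-correction constants c_m: corrected scale = s / c_m.
SCALE_CORRECTION = {0: 1.00, 2: 1.93, 4: 2.74}


def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def corrected_scale(s, degree: int):
    """Corrected scale s/c_m aligning DMA windows with Fourier frequency."""
    if degree not in SCALE_CORRECTION:
        raise ValueError(
            f"unsupported SG degree {degree}; correction constants exist for "
            f"{sorted(SCALE_CORRECTION)}"
        )
    return np.asarray(s, dtype=float) / SCALE_CORRECTION[degree]


def integrate_profile(x: Series1D | np.ndarray) -> Series1D:
    """Cumulative sum turning increments into a profile: y[i] = sum_{j<=i} x[j]."""
    return Series1D(np.cumsum(_values(x)), role="profile")


def sg_smooth(y: Series1D | np.ndarray, degree: int, window: int) -> Series1D:
    """Centred Savitzky-Golay smooth, interior points only.

    Returns the N - window + 1 interior values: index j of the output is the
    smoothed value at input index j + (window-1)//2, i.e. the value at the
    centre of the least-squares polynomial of the given degree fitted over
    the centred window.  Edge samples, where no full window fits, are not
    produced — the fluctuation function never uses them.
    """
    v = _values(y)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if degree >= window:
        raise ValueError(f"degree ({degree}) must be smaller than window ({window})")
    if window > v.size:
        raise ValueError(f"window ({window}) exceeds series length ({v.size})")
    coeffs = _signal.savgol_coeffs(window, degree)
    return Series1D(_signal.fftconvolve(v, coeffs, mode="valid"), role="smoothed")


def sg_residuals(y: np.ndarray, degree: int, window: int) -> np.ndarray:
    """Profile minus its SG smooth on the interior points (length N-s+1)."""
    v = _values(y)
    if window >= v.size:
        raise ValueError(f"scale {window} must be smaller than series length {v.size}")
    half = (window - 1) // 2
    coeffs = _signal.savgol_coeffs(window, degree)
    smooth = _signal.fftconvolve(v, coeffs, mode="valid")
    return v[half : v.size - half] - smooth


def fluctuation_function(x: Series1D | np.ndarray, cfg: DMAConfig) -> FluctuationResult:
    """DMA fluctuation function F(s) over the configured scale grid.

    If ``cfg.integrate`` the series is first cumulatively summed (the
    standard case for increment-like input); pass ``integrate=False`` when
    the input already is an fBm-like path.
    """
    v = _values(x)
    y = np.cumsum(v) if cfg.integrate else v
    n = y.size
    scales = np.asarray(cfg.scales, dtype=int)
    F = np.empty(scales.size)
    for j, s in enumerate(scales):
        r = sg_residuals(y, cfg.degree, int(s))
        # exactly N - s + 1 summands by construction
        F[j] = np.sqrt(np.mean(r * r))
    return FluctuationResult(
        scales=scales,
        corrected_scales=corrected_scale(scales, cfg.degree),
        F=F,
        n=n,
    )


def fit_slope(res: FluctuationResult, lo: float, hi: float) -> SlopeFit:
    """OLS slope of log10 F vs log10 corrected scale on the open interval (lo, hi)."""
    log_s = np.log10(res.corrected_scales)
    mask = (log_s > lo) & (log_s < hi)
    n_points = int(np.count_nonzero(mask))
    if n_points < 2:
        raise ValueError(
            f"need at least 2 scales with {lo} < log10(corrected scale) < {hi}; "
            f"found {n_points}"
        )
    f = res.F[mask]
    if np.any(f <= 0):
        raise ValueError("F(s) = 0 inside the fit range; log-log slope undefined")
    slope, intercept = np.polyfit(log_s[mask], np.log10(f), 1)
    return SlopeFit(
        alpha=float(slope),
        intercept=float(intercept),
        fit_lo=lo,
        fit_hi=hi,
        n_points=n_points,
    )


def local_slopes(res: FluctuationResult) -> tuple[np.ndarray, np.ndarray]:
    """Local log-log slopes between consecutive grid scales.

    Returns (midpoints, slopes): centred two-point finite differences of
    log10 F over log10 corrected scale, each attributed to the midpoint of
    the consecutive log10 corrected scales.
    """
    if np.any(res.F <= 0):
        raise ValueError("F(s) = 0 somewhere; local log-log slopes undefined")
    log_s = np.log10(res.corrected_scales)
    log_f = np.log10(res.F)
    slopes = np.diff(log_f) / np.diff(log_s)
    midpoints = 0.5 * (log_s[1:] + log_s[:-1])
    return midpoints, slopes


def default_scales(
    n: int,
    degree: int = 2,
    per_decade: int = 20,
    s_min: int = 5,
    s_max: int | None = None,
) -> np.ndarray:
    """Odd window lengths nearest to log-spaced points, deduplicated.

    Default coverage runs from s_min (at least degree + 2) up to n // 10,
    with ``per_decade`` grid points per decade — even coverage of the
    log-log fit without oversampling small scales.
    """
    if s_max is None:
        s_max = n // 10
    s_min = max(s_min, degree + 2)
    if s_min % 2 == 0:
        s_min += 1
    if s_max < s_min:
        raise ValueError(f"series too short: need scales in [{s_min}, {s_max}]")
    grid = 10.0 ** np.arange(
        np.log10(s_min), np.log10(s_max) + 1e-12, 1.0 / per_decade
    )
    odd = (2 * np.round((grid - 1) / 2) + 1).astype(int)
    odd = np.unique(odd)
    return odd[(odd >= s_min) & (odd <= s_max)]
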