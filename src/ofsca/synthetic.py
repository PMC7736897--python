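"""Exact simulators for the signal classes used to exercise directional DMA.

Fractional Gaussian noise is generated by circulant embedding of its
autocovariance (Davies-Harte), which reproduces the target spectrum exactly
rather than approximately — a requirement for slope-recovery experiments
where a biased generator would masquerade as an estimator error.  The other
generators (two-component mixed fGn, a damped AR(2) oscillator, a pure
sinusoid, white noise) cover the oscillatory and short-range-correlated
regimes against which the scaling estimator must be validated.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

from .types import AR2Spec, FGnSpec, MixedFGnSpec, Series1D, Trajectory2D

__all__ = [
    "fgn_autocovariance",
    "circulant_eigenvalues",
    "generate_fgn",
    "mix_components",
    "mixed_fgn_spec",
    "generate_mixed_fgn",
    "generate_ar2",
    "ar2_coefficients",
    "ar2_stationary_variance",
    "generate_sinusoid",
    "generate_white_noise",
    "split_seed",
]

#: Relative tolerance for clipping tiny negative circulant eigenvalues.
EIGENVALUE_CLIP_REL = 1e-8


class EmbeddingError(ValueError):
    """Circulant embedding produced a materially negative eigenvalue."""


def fgn_autocovariance(lags, hurst: float, sigma: float = 1.0) -> np.ndarray:
    """Closed-form fGn autocovariance gamma(k).

    gamma(k) = (sigma^2 / 2) (|k+1|^{2H} - 2 |k|^{2H} + |k-1|^{2H}).
    At H = 0.5 this vanishes for every non-zero lag (white noise).
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * sigma**2 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


def circulant_eigenvalues(spec: FGnSpec) -> np.ndarray:
    """Eigenvalues of the circulant embedding of the fGn covariance.

    The first row of the embedding circulant is
    [gamma(0), ..., gamma(n-1), gamma(n-2), ..., gamma(1)] (length 2n-2);
    its eigenvalues are the real DFT of that row.  They must be
    non-negative for the embedding to define a valid Gaussian law.
    """
    gamma = fgn_autocovariance(np.arange(spec.n), spec.hurst, spec.sigma)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    return np.fft.fft(row).real


def generate_fgn(spec: FGnSpec) -> Series1D:
    """Sample exact fractional Gaussian noise by circulant embedding.

    Eigenvalues in [-EIGENVALUE_CLIP_REL * max, 0) are clipped to zero
    (floating-point dust); anything more negative raises
    :class:`EmbeddingError` rather than silently distorting the spectrum.
    The draw is bit-reproducible for a fixed ``spec.seed``.
    """
    lam = circulant_eigenvalues(spec)
    m = lam.size
    lam_max = lam.max()
    if lam.min() < -EIGENVALUE_CLIP_REL * lam_max:
        raise EmbeddingError(
            f"circulant embedding has negative eigenvalue {lam.min():.3e} "
            f"(H={spec.hurst}, n={spec.n}); cannot sample exactly"
        )
    lam = np.clip(lam, 0.0, None)

    rng = np.random.default_rng(spec.seed)
    half = m // 2  # m = 2(n-1) is even
    w = np.empty(m, dtype=complex)
    w[0] = rng.standard_normal()
    w[half] = rng.standard_normal()
    if half > 1:
        re = rng.standard_normal(half - 1)
        im = rng.standard_normal(half - 1)
        w[1:half] = (re + 1j * im) / np.sqrt(2.0)
        w[half + 1 :] = np.conj(w[1:half][::-1])
    y = np.fft.ifft(np.sqrt(lam) * w) * np.sqrt(m)
    return Series1D(y.real[: spec.n].copy(), role="increments")


def mix_components(
    eps1: Series1D | np.ndarray,
    eps2: Series1D | np.ndarray,
    theta1: float,
    theta2: float,
) -> Trajectory2D:
    """Mix two component series oriented at angles theta1, theta2.

    x1 = eps1 cos(theta1) + eps2 cos(theta2)
    x2 = eps1 sin(theta1) + eps2 sin(theta2)

    The angles need not be orthogonal; parallel angles produce a degenerate
    rank-1 trajectory, which is permitted here (the *decomposition* is what
    becomes ill-posed, and it guards separately).
    """
    e1 = np.asarray(getattr(eps1, "values", eps1), dtype=float)
    e2 = np.asarray(getattr(eps2, "values", eps2), dtype=float)
    if e1.size != e2.size:
        raise ValueError(f"component lengths differ ({e1.size} != {e2.size})")
    x1 = e1 * np.cos(theta1) + e2 * np.cos(theta2)
    x2 = e1 * np.sin(theta1) + e2 * np.sin(theta2)
    return Trajectory2D(x1, x2, kind="increments")


def split_seed(seed: int, n_children: int = 2) -> list[int]:
    """Derive independent child seeds from one user seed.

    Deterministic: numpy ``SeedSequence`` spawning, with each child reduced
    to a non-negative 31-bit integer.
    """
    children = np.random.SeedSequence(seed).spawn(n_children)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def mixed_fgn_spec(
    h1: float,
    theta1: float,
    h2: float,
    theta2: float,
    n: int,
    seed: int = 0,
    sigma1: float = 1.0,
    sigma2: float = 1.0,
) -> MixedFGnSpec:
    """Build a two-component mixed-fGn spec from a single seed.

    The two component streams get independent seeds via :func:`split_seed`.
    """
    s1, s2 = split_seed(seed, 2)
    if s1 == s2:  # astronomically unlikely; keep the independence invariant
        s2 = (s2 + 1) & 0x7FFFFFFF
    return MixedFGnSpec(
        spec1=FGnSpec(hurst=h1, n=n, sigma=sigma1, seed=s1),
        spec2=FGnSpec(hurst=h2, n=n, sigma=sigma2, seed=s2),
        theta1=theta1,
        theta2=theta2,
    )


def generate_mixed_fgn(spec: MixedFGnSpec) -> Trajectory2D:
    """Sample the two independent fGn components and mix them."""
    eps1 = generate_fgn(spec.spec1)
    eps2 = generate_fgn(spec.spec2)
    return mix_components(eps1, eps2, spec.theta1, spec.theta2)


def ar2_coefficients(spec: AR2Spec) -> tuple[float, float]:
    """AR coefficients (a1, a2) for complex poles at radius r, period p."""
    a1 = 2.0 * spec.pole_radius * np.cos(2.0 * np.pi / spec.period)
    a2 = -spec.pole_radius**2
    return a1, a2


def ar2_stationary_variance(spec: AR2Spec) -> float:
    """Closed-form stationary variance of the AR(2) process (Yule-Walker)."""
    a1, a2 = ar2_coefficients(spec)
    return spec.sigma**2 * (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1**2))


def generate_ar2(spec: AR2Spec) -> Series1D:
    """Simulate the AR(2) oscillator, discarding a burn-in of 10 periods.

    With a pole radius near 1 the spectrum falls as f^-4 above the resonance,
    the regime in which higher-order DMA reads a scaling exponent of 2.5.
    """
    a1, a2 = ar2_coefficients(spec)
    burn = int(np.ceil(10.0 * spec.period))
    rng = np.random.default_rng(spec.seed)
    noise = spec.sigma * rng.standard_normal(spec.n + burn)
    x = _signal.lfilter([1.0], [1.0, -a1, -a2], noise)[burn:]
    return Series1D(x, role="increments")


def generate_sinusoid(
    period: float, amplitude: float = 1.0, n: int = 1024, phase: float = 0.0
) -> Series1D:
    """x[i] = A sin(2 pi i / p + phi), i = 0..n-1."""
    if period <= 2:
        raise ValueError("period must exceed 2 samples")
    i = np.arange(n, dtype=float)
    return Series1D(amplitude * np.sin(2.0 * np.pi * i / period + phase), role="increments")


def generate_white_noise(n: int, sigma: float = 1.0, seed: int = 0) -> Series1D:
    """IID Gaussian noise — the short-range-correlated reference signal."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    return Series1D(sigma * rng.standard_normal(n), role="increments")
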