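"""Domain containers for oriented fractal scaling component analysis.

The objects here are thin, validated dataclasses around numpy arrays.  All
angles are stored in radians and wrapped to [0, pi); conversion to degrees
happens only at the reporting/CLI layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Series1D",
    "Trajectory2D",
    "FGnSpec",
    "MixedFGnSpec",
    "AR2Spec",
    "DMAConfig",
    "FluctuationResult",
    "SlopeFit",
    "DirectionalScan",
    "OrientationResult",
    "Decomposition",
    "OFSCAResult",
]

_SERIES_ROLES = ("increments", "profile", "smoothed")
_TRAJ_KINDS = ("increments", "path")


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.ascontiguousarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class Series1D:
    """A uniformly sampled real-valued signal with a processing-stage tag.

    The ``role`` records where the series sits in the DMA pipeline:
    ``increments`` (raw, fGn-like), ``profile`` (cumulatively summed,
    fBm-like) or ``smoothed`` (output of the Savitzky-Golay filter).
    """

    values: np.ndarray
    role: str = "increments"

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values")
        if self.values.size < 2:
            raise ValueError("a series needs at least 2 samples")
        if self.role not in _SERIES_ROLES:
            raise ValueError(f"role must be one of {_SERIES_ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Trajectory2D:
    """Paired series (x1, x2): the 2D trajectory the analysis consumes.

    ``kind='increments'`` means the samples are displacement increments and
    the profile must be built by cumulative summation before detrending;
    ``kind='path'`` means the samples already trace an fBm-like path and the
    integration step is skipped.
    """

    x1: np.ndarray
    x2: np.ndarray
    kind: str = "increments"

    def __post_init__(self) -> None:
        self.x1 = _as_float_array(self.x1, "x1")
        self.x2 = _as_float_array(self.x2, "x2")
        if self.x1.size != self.x2.size:
            raise ValueError(
                f"x1 and x2 must have equal length ({self.x1.size} != {self.x2.size})"
            )
        if self.x1.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if self.kind not in _TRAJ_KINDS:
            raise ValueError(f"kind must be one of {_TRAJ_KINDS}, got {self.kind!r}")

    def __len__(self) -> int:
        return self.x1.size


@dataclass
class FGnSpec:
    """Parameters of one fractional Gaussian noise realisation."""

    hurst: float
    n: int
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must be in (0,1)")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class MixedFGnSpec:
    """Two independent fGn components mixed at (generally non-orthogonal) angles."""

    spec1: FGnSpec
    spec2: FGnSpec
    theta1: float
    theta2: float

    def __post_init__(self) -> None:
        if self.spec1.n != self.spec2.n:
            raise ValueError("both components must have the same length")
        for name in ("theta1", "theta2"):
            v = getattr(self, name)
            if not 0.0 <= v < np.pi:
                raise ValueError(f"{name} must be in [0, pi), got {v}")
        if abs(np.sin(self.theta1 - self.theta2)) < 1e-12:
            raise ValueError("mixing angles must not be parallel (mod pi)")
        if self.spec1.seed == self.spec2.seed:
            raise ValueError("component seeds must differ (independence)")


@dataclass
class AR2Spec:
    """A damped stochastic oscillator: AR(2) with complex poles.

    The poles sit at radius ``pole_radius`` and angle ``2*pi/period``, i.e.
    x[i] = a1 x[i-1] + a2 x[i-2] + sigma xi[i] with a1 = 2 r cos(2 pi / p)
    and a2 = -r^2.
    """

    period: float
    n: int
    pole_radius: float = 0.995
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 2:
            raise ValueError("period must exceed 2 samples")
        if not 0.0 <= self.pole_radius < 1.0:
            raise ValueError("pole_radius must be in [0,1) for stationarity")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass
class DMAConfig:
    """Configuration of one Savitzky-Golay DMA pass.

    ``degree`` is the SG polynomial order m (0, 2 or 4 — the orders with
    published scale-correction constants); ``scales`` are odd window lengths;
    ``fit_range`` is the open interval (lo, hi) in log10 corrected-scale
    units used for the global slope fit; ``integrate`` applies the
    cumulative-sum profile step before detrending.
    """

    degree: int = 2
    scales: Sequence[int] = field(default_factory=list)
    fit_range: tuple[float, float] = (1.0, 3.0)
    integrate: bool = True

    def __post_init__(self) -> None:
        if self.degree not in (0, 2, 4):
            raise ValueError("degree must be 0, 2 or 4")
        scales = np.asarray(self.scales, dtype=int)
        if scales.size == 0:
            raise ValueError("scales must be non-empty")
        if np.any(scales % 2 == 0):
            raise ValueError("all scales must be odd")
        if np.any(scales < self.degree + 2):
            raise ValueError(f"all scales must be >= degree + 2 = {self.degree + 2}")
        if np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        self.scales = scales
        lo, hi = self.fit_range
        if not lo < hi:
            raise ValueError("fit_range must satisfy lo < hi")


@dataclass
class FluctuationResult:
    """F(s) for one series: window sizes, corrected scales and fluctuations."""

    scales: np.ndarray
    corrected_scales: np.ndarray
    F: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.corrected_scales = np.asarray(self.corrected_scales, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if not (self.scales.size == self.corrected_scales.size == self.F.size):
            raise ValueError("scales, corrected_scales and F must align")
        if np.any(self.F < 0):
            raise ValueError("fluctuation values must be non-negative")
        if self.scales.max() >= self.n:
            raise ValueError("largest scale must be smaller than the series length")


@dataclass
class SlopeFit:
    """An ordinary least-squares slope of log10 F vs log10 corrected scale."""

    alpha: float
    intercept: float
    fit_lo: float
    fit_hi: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a slope fit needs at least 2 points")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "intercept": self.intercept,
            "fit_lo": self.fit_lo,
            "fit_hi": self.fit_hi,
            "n_points": self.n_points,
        }


@dataclass
class DirectionalScan:
    """Angle-resolved DMA: F(theta, s), global slopes and local slopes.

    ``F_matrix`` has one row per angle and one column per scale.
    ``local_slope_matrix`` holds centred finite differences of log10 F over
    log10 corrected scale; ``local_slope_log_scales`` are the midpoints of
    consecutive log10 corrected scales those slopes refer to.
    """

    angles: np.ndarray
    scales: np.ndarray
    corrected_scales: np.ndarray
    F_matrix: np.ndarray
    alpha: np.ndarray
    local_slope_matrix: np.ndarray
    local_slope_log_scales: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any((self.angles < 0) | (self.angles >= np.pi)):
            raise ValueError("angles must lie in [0, pi)")
        if self.F_matrix.shape != (self.angles.size, self.corrected_scales.size):
            raise ValueError("F_matrix must be (n_angles, n_scales)")
        if np.any(self.F_matrix < 0):
            raise ValueError("F_matrix must be non-negative")
        if self.alpha.size != self.angles.size:
            raise ValueError("alpha must have one value per angle")


@dataclass
class OrientationResult:
    """Detected extremal-slope angles and the inferred component orientations.

    The component orientations are orthogonal to the extremal-slope angles:
    theta1_hat = theta_min + pi/2 (mod pi), theta2_hat = theta_max + pi/2
    (mod pi).
    """

    theta_min: float
    theta_max: float
    alpha_min: float
    alpha_max: float
    theta1_hat: float
    theta2_hat: float

    def __post_init__(self) -> None:
        for name in ("theta_min", "theta_max", "theta1_hat", "theta2_hat"):
            v = getattr(self, name)
            if not 0.0 <= v < np.pi:
                raise ValueError(f"{name} must be in [0, pi), got {v}")
        if self.alpha_min > self.alpha_max:
            raise ValueError("alpha_min must not exceed alpha_max")

    def to_dict(self) -> dict:
        deg = 180.0 / np.pi
        return {
            "theta_min_deg": self.theta_min * deg,
            "theta_max_deg": self.theta_max * deg,
            "theta1_deg": self.theta1_hat * deg,
            "theta2_deg": self.theta2_hat * deg,
            "alpha_min": self.alpha_min,
            "alpha_max": self.alpha_max,
        }


@dataclass
class Decomposition:
    """Reconstructed oriented components and the unmixing matrix used."""

    eps1_hat: Series1D
    eps2_hat: Series1D
    unmixing: np.ndarray
    cross_corr: float

    def __post_init__(self) -> None:
        self.unmixing = np.asarray(self.unmixing, dtype=float)
        if self.unmixing.shape != (2, 2):
            raise ValueError("unmixing must be a 2x2 matrix")
        if abs(self.cross_corr) > 1.0 + 1e-12:
            raise ValueError("|cross_corr| must not exceed 1")


@dataclass
class OFSCAResult:
    """End-to-end pipeline output: scan, orientations, decomposition, fits."""

    scan: DirectionalScan
    orientation: OrientationResult
    decomposition: Decomposition
    component_fluctuations: tuple[FluctuationResult, FluctuationResult]
    component_fits: tuple[SlopeFit, SlopeFit]
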