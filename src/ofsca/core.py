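"""Orientation detection and closed-form decomposition (the OFSCA step).

For a two-component mixture

    [x1; x2] = [[cos t1, cos t2], [sin t1, sin t2]] [eps1; eps2],

the projection at angle t is eps1 cos(t - t1) + eps2 cos(t - t2).  At
t = t1 + pi/2 the first component drops out entirely and the projection is
a pure (rescaled) copy of eps2 — and symmetrically at t = t2 + pi/2 for
eps1.  Everywhere else the projection is a genuine mixture whose forced
log-log slope lands between the two component exponents.  The slope
profile alpha(theta) therefore attains its extrema at the angles
orthogonal to the component orientations: the detected theta_min and
theta_max, shifted by 90 degrees (mod 180), estimate t1 and t2.  Inverting
the mixing matrix at the estimated angles recovers the components in
closed form — no orthogonality between t1 and t2 is required, which is
precisely where PCA/ICA fail for Gaussian mixtures.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .dma import default_scales, fit_slope, fluctuation_function
from .types import (
    Decomposition,
    DirectionalScan,
    DMAConfig,
    OFSCAResult,
    OrientationResult,
    Series1D,
    Trajectory2D,
)

__all__ = [
    "NoAnisotropyError",
    "DegenerateAnglesError",
    "detect_orientations",
    "unmixing_matrix",
    "decompose",
    "run_ofsca",
]

#: Minimum spread of alpha(theta) below which no orientation is declared.
FLATNESS_THRESHOLD = 0.02

#: Minimum |sin(theta2 - theta1)| for a well-posed unmixing.
MIN_ANGLE_SEPARATION_SIN = 1e-6


class NoAnisotropyError(ValueError):
    """alpha(theta) is too flat to identify orientations."""


class DegenerateAnglesError(ValueError):
    """The two estimated orientations are (nearly) parallel."""


def detect_orientations(
    scan: DirectionalScan, flatness_threshold: float = FLATNESS_THRESHOLD
) -> OrientationResult:
    """Locate the extremal-slope angles and the orthogonal component axes.

    theta_min / theta_max are the grid argmin / argmax of alpha(theta)
    (ties broken toward the smaller angle index); the component orientations
    are those angles shifted by +pi/2 and wrapped into [0, pi).  Raises
    :class:`NoAnisotropyError` when max(alpha) - min(alpha) falls below the
    flatness threshold — an isotropic trajectory has no preferred axes.
    """
    alpha = np.asarray(scan.alpha, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("alpha(theta) contains non-finite values")
    k_min = int(np.argmin(alpha))
    k_max = int(np.argmax(alpha))
    spread = alpha[k_max] - alpha[k_min]
    if spread < flatness_threshold:
        raise NoAnisotropyError(
            f"no detectable anisotropy: max-min slope spread {spread:.4f} "
            f"< {flatness_threshold}"
        )
    theta_min = float(scan.angles[k_min])
    theta_max = float(scan.angles[k_max])
    return OrientationResult(
        theta_min=theta_min,
        theta_max=theta_max,
        alpha_min=float(alpha[k_min]),
        alpha_max=float(alpha[k_max]),
        theta1_hat=(theta_min + np.pi / 2) % np.pi,
        theta2_hat=(theta_max + np.pi / 2) % np.pi,
    )


def unmixing_matrix(theta1_hat: float, theta2_hat: float) -> np.ndarray:
    """Inverse of the 2x2 mixing matrix at the estimated orientations.

    M = [[ sin(t2)/sin(t2-t1),  cos(t2)/sin(t1-t2)],
         [ sin(t1)/sin(t1-t2),  cos(t1)/sin(t2-t1)]]
    """
    d = np.sin(theta2_hat - theta1_hat)
    if abs(d) < MIN_ANGLE_SEPARATION_SIN:
        raise DegenerateAnglesError(
            f"degenerate decomposition: |sin(theta2-theta1)| = {abs(d):.2e} "
            f"too small"
        )
    return np.array(
        [
            [np.sin(theta2_hat) / d, -np.cos(theta2_hat) / d],
            [-np.sin(theta1_hat) / d, np.cos(theta1_hat) / d],
        ]
    )


def decompose(
    traj: Trajectory2D, theta1_hat: float, theta2_hat: float
) -> Decomposition:
    """Recover the oriented components by applying the unmixing matrix.

    Also reports the Pearson cross-correlation of the two reconstructed
    components — near zero when the estimated angles match the true ones.
    """
    m = unmixing_matrix(theta1_hat, theta2_hat)
    comps = m @ np.vstack([traj.x1, traj.x2])
    role = "increments" if traj.kind == "increments" else "profile"
    cross = float(np.corrcoef(comps[0], comps[1])[0, 1])
    return Decomposition(
        eps1_hat=Series1D(comps[0], role=role),
        eps2_hat=Series1D(comps[1], role=role),
        unmixing=m,
        cross_corr=cross,
    )


def run_ofsca(
    traj: Trajectory2D,
    cfg: DMAConfig | None = None,
    n_angles: int = 64,
    flatness_threshold: float = FLATNESS_THRESHOLD,
    method: str = "bilinear",
) -> OFSCAResult:
    """End-to-end pipeline: angle scan, orientation detection, decomposition.

    After unmixing, each reconstructed component is rerun through the
    one-dimensional DMA with the same configuration and its slope refit,
    giving the component scaling exponents.  With ``cfg=None`` a default
    second-order configuration with a log-spaced scale grid up to a tenth
    of the series length and fit range 1 < log10(corrected scale) < 3 is
    used.
    """
    from .ddma import angle_scan  # local import to avoid a cycle at module load

    if cfg is None:
        cfg = DMAConfig(degree=2, scales=default_scales(len(traj)), fit_range=(1.0, 3.0))
    scan = angle_scan(traj, cfg, n_angles=n_angles, method=method)
    orientation = detect_orientations(scan, flatness_threshold)
    decomp = decompose(traj, orientation.theta1_hat, orientation.theta2_hat)

    comp_cfg = replace(cfg, integrate=(traj.kind == "increments"))
    res1 = fluctuation_function(decomp.eps1_hat, comp_cfg)
    res2 = fluctuation_function(decomp.eps2_hat, comp_cfg)
    lo, hi = cfg.fit_range
    fit1 = fit_slope(res1, lo, hi)
    fit2 = fit_slope(res2, lo, hi)
    return OFSCAResult(
        scan=scan,
        orientation=orientation,
        decomposition=decomp,
        component_fluctuations=(res1, res2),
        component_fits=(fit1, fit2),
    )
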