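"""Independent brute-force oracles the implementation is pinned against.

Everything here is a literal, slow transcription of the defining formulas
(per-window least squares, loop-based fluctuation sums, normal-equations
regression) and shares no code path with the package internals.
"""

import numpy as np


def windowed_polyfit_smooth(y: np.ndarray, degree: int, window: int) -> np.ndarray:
    """Per-window least-squares smooth: value at the centre of each fit."""
    y = np.asarray(y, dtype=float)
    half = (window - 1) // 2
    t = np.arange(-half, half + 1, dtype=float)
    out = np.empty(y.size - window + 1)
    for j in range(out.size):
        coeffs = np.polyfit(t, y[j : j + window], degree)
        out[j] = np.polyval(coeffs, 0.0)
    return out


def brute_fluctuation(x, degree: int, scales, integrate: bool = True) -> np.ndarray:
    """Loop-based transcription of the DMA fluctuation function.

    F(s) = sqrt( (1/(N-s+1)) * sum over the N-s+1 centred windows of
    (y[centre] - fitted-polynomial value at the centre)^2 ).
    """
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x) if integrate else x
    n = y.size
    F = []
    for s in scales:
        half = (s - 1) // 2
        t = np.arange(-half, half + 1, dtype=float)
        total = 0.0
        count = 0
        for i in range(half, n - half):
            coeffs = np.polyfit(t, y[i - half : i + half + 1], degree)
            total += (y[i] - np.polyval(coeffs, 0.0)) ** 2
            count += 1
        assert count == n - s + 1
        F.append(np.sqrt(total / count))
    return np.asarray(F)


def normal_equations_slope(x, y) -> tuple[float, float]:
    """OLS slope/intercept from the explicit normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def ar2_variance_yule_walker(a1: float, a2: float, sigma: float) -> float:
    """Stationary AR(2) variance by numerically solving the Yule-Walker system.

    Unknowns (gamma0, gamma1, gamma2):
        gamma0 = a1 gamma1 + a2 gamma2 + sigma^2
        gamma1 = a1 gamma0 + a2 gamma1
        gamma2 = a1 gamma1 + a2 gamma0
    """
    A = np.array(
        [
            [1.0, -a1, -a2],
            [-a1, 1.0 - a2, 0.0],
            [-a2, -a1, 1.0],
        ]
    )
    b = np.array([sigma**2, 0.0, 0.0])
    gamma = np.linalg.solve(A, b)
    return float(gamma[0])
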