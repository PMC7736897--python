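"""Optional flat heat-map helper for directional scans (needs matplotlib)."""

from __future__ import annotations

import numpy as np

from .types import DirectionalScan


def plot_scan_heatmap(scan: DirectionalScan, ax=None, local_slopes: bool = False):
    """Heat map of log10 F (or local slopes) over angle and log10 scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if local_slopes:
        z = scan.local_slope_matrix
        x = scan.local_slope_log_scales
        label = "local slope"
    else:
        z = np.log10(np.where(scan.F_matrix > 0, scan.F_matrix, np.nan))
        x = np.log10(scan.corrected_scales)
        label = r"$\log_{10} F^{(\theta)}(\tilde{s})$"
    mesh = ax.pcolormesh(x, np.degrees(scan.angles), z, shading="nearest")
    ax.set_xlabel(r"$\log_{10} \tilde{s}$")
    ax.set_ylabel(r"$\theta$ (deg)")
    ax.figure.colorbar(mesh, ax=ax, label=label)
    return ax
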