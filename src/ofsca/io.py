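"""Delimited-text I/O and report serialisation.

All interchange formats are plain text: two-column CSV/TSV for
trajectories, single-column for series, wide CSV tables for directional
scans, JSON for reports and slope fits.  Numeric output always uses the
period as decimal separator, independent of locale.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DirectionalScan,
    FluctuationResult,
    OFSCAResult,
    Series1D,
    SlopeFit,
    Trajectory2D,
)

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_series",
    "write_series",
    "fluctuation_to_frame",
    "scan_to_frame",
    "alpha_profile_frame",
    "ofsca_report",
]

logger = logging.getLogger(__name__)

_DEG = 180.0 / np.pi


def _sniff_delimiter(line: str) -> str:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    if ";" in line:
        return ";"
    return r"\s+"


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_trajectory(
    path: str | Path,
    delimiter: str | None = None,
    columns: tuple[int, int] = (0, 1),
    kind: str = "increments",
    drop_bad: bool = False,
) -> Trajectory2D:
    """Read a two-column delimited text file into a trajectory.

    The delimiter is auto-detected (comma, tab, semicolon or whitespace)
    unless given; a single header line is detected and skipped.  Rows with
    NaN/Inf values are dropped with a logged count when ``drop_bad`` is
    set, otherwise they raise.  Non-numeric cells always raise, naming the
    offending line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    sep = delimiter if delimiter is not None else _sniff_delimiter(first)
    tokens = [t for t in first.strip().split(sep if sep != r"\s+" else None) if t]
    has_header = not all(_is_number(t) for t in tokens)

    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep == r"\s+" else "c",
        header=0 if has_header else None,
        dtype=str,
        skip_blank_lines=True,
        comment="#",
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns, found {df.shape[1]}")
    c1, c2 = columns
    data_start_line = 2 if has_header else 1  # 1-based line of the first data row
    cols = []
    for c in (c1, c2):
        raw = df.iloc[:, c].astype(str).str.strip()
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & ~raw.str.lower().isin(["nan", "-nan", ""])
        if bad.any():
            line_no = int(bad.idxmax()) + data_start_line
            raise ValueError(
                f"{path}: non-numeric value {raw[bad.idxmax()]!r} at line {line_no}"
            )
        cols.append(num.to_numpy(dtype=float))
    x1, x2 = cols
    finite = np.isfinite(x1) & np.isfinite(x2)
    n_bad = int(np.count_nonzero(~finite))
    if n_bad:
        if not drop_bad:
            line_no = int(np.argmin(finite)) + data_start_line
            raise ValueError(
                f"{path}: {n_bad} row(s) with NaN/Inf (first at line {line_no}); "
                f"pass drop_bad=True to discard them"
            )
        logger.warning("%s: dropped %d row(s) with NaN/Inf values", path, n_bad)
        x1, x2 = x1[finite], x2[finite]
    return Trajectory2D(x1, x2, kind=kind)


def write_trajectory(
    path: str | Path, traj: Trajectory2D, delimiter: str = ","
) -> None:
    """Write a trajectory as two-column delimited text with header ``x1,x2``."""
    header = delimiter.join(["x1", "x2"])
    np.savetxt(
        path,
        np.column_stack([traj.x1, traj.x2]),
        delimiter=delimiter,
        header=header,
        comments="",
        fmt="%.17g",
    )


def write_series(path: str | Path, series: Series1D, delimiter: str = ",") -> None:
    """Write a series as single-column text with header ``x``."""
    np.savetxt(path, series.values, header="x", comments="", fmt="%.17g")


def read_series(path: str | Path, role: str = "increments") -> Series1D:
    """Read a single-column text file (optional one-line header) into a series."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = not _is_number(first.strip().split(",")[0])
    values = np.loadtxt(path, skiprows=1 if has_header else 0, delimiter=None)
    return Series1D(np.atleast_1d(values), role=role)


def fluctuation_to_frame(res: FluctuationResult) -> pd.DataFrame:
    """Columns s, s_corrected, F — the serialisable form of F(s)."""
    return pd.DataFrame(
        {"s": res.scales, "s_corrected": res.corrected_scales, "F": res.F}
    )


def scan_to_frame(scan: DirectionalScan) -> pd.DataFrame:
    """Wide table of F(theta, s): rows angles in degrees, columns corrected scales."""
    df = pd.DataFrame(
        scan.F_matrix,
        index=np.round(scan.angles * _DEG, 6),
        columns=np.round(scan.corrected_scales, 6),
    )
    df.index.name = "theta_deg"
    return df


def alpha_profile_frame(scan: DirectionalScan) -> pd.DataFrame:
    """Two-column table theta (degrees), alpha(theta)."""
    return pd.DataFrame({"theta_deg": scan.angles * _DEG, "alpha": scan.alpha})


def ofsca_report(result: OFSCAResult) -> dict:
    """JSON-ready summary of one OFSCA run."""
    ori = result.orientation
    fit1, fit2 = result.component_fits
    return {
        "theta_min_deg": ori.theta_min * _DEG,
        "theta_max_deg": ori.theta_max * _DEG,
        "theta1_deg": ori.theta1_hat * _DEG,
        "theta2_deg": ori.theta2_hat * _DEG,
        "alpha_min": ori.alpha_min,
        "alpha_max": ori.alpha_max,
        "alpha_profile": {
            "theta_deg": (result.scan.angles * _DEG).tolist(),
            "alpha": result.scan.alpha.tolist(),
        },
        "component_alphas": [fit1.alpha, fit2.alpha],
        "component_fits": [fit1.to_dict(), fit2.to_dict()],
        "cross_corr": result.decomposition.cross_corr,
    }


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
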