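"""Shared readers and writers for trajectory CSV, ring CSV and JSON reports.

All numeric serialisation uses 12+ significant digits so that values survive
a write/read round trip at the precision the model comparisons need.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .model_core import Trajectory

__all__ = [
    "FLOAT_FORMAT",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_rings_csv",
    "read_rings_csv",
    "write_json_report",
]

#: 12 significant digits in scientific notation (13 total).
FLOAT_FORMAT = "%.12e"


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write ``t,V_m,V_b_I,V_b_II,V_total`` rows, one per time point."""
    traj.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["t", "V_m", "V_b_I", "V_b_II", "V_total"]
    if list(df.columns) != expected:
        raise DataError(f"trajectory CSV must have columns {expected}, got {list(df.columns)}")
    return df


def write_rings_csv(radii, path: str | Path) -> None:
    """Write ring radii as ``j,radius`` rows with j = 1, 2, ...."""
    radii = np.asarray(radii, dtype=float)
    df = pd.DataFrame({"j": np.arange(1, radii.size + 1), "radius": radii})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_rings_csv(path: str | Path) -> np.ndarray:
    """Read ring radii from CSV.

    Accepts either the ``j,radius`` dialect (rows are sorted by j) or a
    single ``radius`` column / headerless single column (j taken positional).
    """
    df = pd.read_csv(path)
    cols = [str(c).strip().lower() for c in df.columns]
    if "radius" in cols:
        df.columns = cols
        if "j" in cols:
            df = df.sort_values("j")
        radii = df["radius"].to_numpy(dtype=float)
    elif len(cols) == 1:
        # headerless single column: the "header" cell is the first value
        try:
            first = float(cols[0])
        except ValueError as exc:
            raise DataError(
                f"ring CSV must have a 'radius' column or one numeric column, "
                f"got columns {cols}"
            ) from exc
        radii = np.concatenate([[first], df.iloc[:, 0].to_numpy(dtype=float)])
    else:
        raise DataError(
            f"ring CSV must have a 'radius' column (optionally with 'j'), got {cols}"
        )
    if radii.size == 0:
        raise DataError("ring CSV contains no radii")
    return radii


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")


def write_json_report(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_json_default) + "\n")
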