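"""Configuration files, CSV writers and legacy-VTK snapshot output.

The configuration is a nested YAML document mirroring
:class:`~memrelo.transport.SimulationConfig`; all densities are in
molecules/µm², energies in J/mol, lengths in µm and times in s.  Totals are
written as CSV with units spelled out in the header comment; mesh snapshots
use the ASCII legacy-VTK polyline format, one file per output time, readable
by ParaView.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemistry import ChemistryParams
from .geometry import KinematicsFrame, StagePlan
from .transport import SimulationConfig, Trajectory

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "write_totals_csv",
    "read_totals_csv",
    "write_vtk_snapshot",
    "write_schedule_csv",
]

TOTALS_COLUMNS = [
    "t",            # s
    "N_R_free",     # molecules
    "N_C",          # molecules
    "N_L_free",     # molecules
    "N_L_available",  # molecules
    "contact_area",   # µm²
    "norm_complex",   # dimensionless, N_C / N_C(t_norm)
]


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["chemistry"] = dataclasses.asdict(config.chemistry)
    plan = dataclasses.asdict(config.plan)
    plan["dt_stage"] = list(config.plan.dt_stage)
    d["plan"] = plan
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    chem = d.pop("chemistry", {}) or {}
    plan = dict(d.pop("plan", {}) or {})
    if "dt_stage" in plan:
        plan["dt_stage"] = tuple(plan["dt_stage"])
    if isinstance(plan.get("substeps"), list):
        plan["substeps"] = tuple(plan["substeps"])
    return SimulationConfig(
        chemistry=ChemistryParams(**chem), plan=StagePlan(**plan), **d
    )


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def write_totals_csv(traj: Trajectory, path, t_norm: float = 1800.0) -> None:
    """Write the trajectory totals with the documented column schema.

    The ``norm_complex`` column is filled only when ``t_norm`` lies inside
    the trajectory (NaN otherwise).  Full float precision is kept so a
    reload reproduces the totals bit for bit.
    """
    df = traj.totals.copy()
    t = df["t"].to_numpy()
    if t[0] <= t_norm <= t[-1]:
        ref = df["N_C"].iloc[int(np.argmin(np.abs(t - t_norm)))]
        df["norm_complex"] = df["N_C"] / ref if ref > 0 else np.nan
    else:
        df["norm_complex"] = np.nan
    header = (
        "# t [s], N_R_free [molecules], N_C [molecules], N_L_free [molecules], "
        "N_L_available [molecules], contact_area [um^2], norm_complex [-]\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df[TOTALS_COLUMNS].to_csv(fh, index=False, float_format="%.17g")


def read_totals_csv(path) -> pd.DataFrame:
    # round_trip parsing keeps the reload bit-identical to what was written
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_schedule_csv(frames, path) -> None:
    """Serialize a sequence of kinematics frames (t, a, h, R_s, area, lambda_a)."""
    rows = []
    for fr in frames:
        rows.append({
            "t": fr.t, "a": fr.cap.a, "h": fr.cap.h, "R_s": fr.cap.R_s,
            "area": fr.cap.total_area, "lambda_a": float(fr.lambda_a[0]),
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_vtk_snapshot(frame: KinematicsFrame, path, point_data: dict | None = None) -> None:
    """Write the meridian polyline with per-node fields as ASCII legacy VTK.

    Nodes are embedded in 3D as (rho, y, 0); the meridian connectivity is a
    single polyline.  ``point_data`` maps field names to per-node arrays
    (e.g. c_R, c_L, c_C, g_N, lambda_a).
    """
    n = frame.rho.size
    lines = [
        "# vtk DataFile Version 3.0",
        f"membrane meridian at t={frame.t} s",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    for rho, y in zip(frame.rho, frame.y):
        lines.append(f"{rho:.17g} {y:.17g} 0")
    lines.append(f"LINES 1 {n + 1}")
    lines.append(" ".join([str(n)] + [str(i) for i in range(n)]))
    data = {"g_N": frame.g_N, "lambda_a": frame.lambda_a}
    if point_data:
        data.update(point_data)
    lines.append(f"POINT_DATA {n}")
    for name, values in data.items():
        values = np.asarray(values, dtype=float)
        if values.size != n:
            raise ValueError(f"point data {name!r} has wrong length")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.17g}" for v in values)
    Path(path).write_text("\n".join(lines) + "\n")
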