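"""Field integration, normalized complex curves and radial ring profiles.

Referential concentrations integrate to molecule counts against the nodal
reference-area weights without a Jacobian; current-configuration densities
(what a basal micrograph shows) are the referential ones divided by the
areal stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import KinematicsFrame, ReferenceSphereMesh

__all__ = [
    "Totals",
    "integrate_totals",
    "normalized_complex_curve",
    "ring_profile",
    "apical_free_fraction",
]


@dataclass(frozen=True)
class Totals:
    """Molecule counts over the whole membrane at one instant."""

    t: float
    N_R_free: float
    N_C: float
    N_L_free: float
    N_L_available: float
    contact_area: float = np.nan


def integrate_totals(state, mesh: ReferenceSphereMesh, contact_area: float = np.nan) -> Totals:
    """Quadrature of the referential fields: ``N_x = sum_i w_i c_x,i``."""
    w = mesh.weights
    for name in ("c_R", "c_L", "c_C", "S_L"):
        if getattr(state, name).shape != w.shape:
            raise ValueError(f"field {name} and mesh weights differ in length")
    return Totals(
        t=state.t,
        N_R_free=float(w @ state.c_R),
        N_C=float(w @ state.c_C),
        N_L_free=float(w @ state.c_L),
        N_L_available=float(w @ state.S_L),
        contact_area=contact_area,
    )


def normalized_complex_curve(traj, t_norm: float = 1800.0) -> pd.Series:
    """Total complex count over time, normalized to unity at ``t_norm``.

    Mirrors the normalization used to compare the simulated complex build-up
    with basal fluorescence measurements; the normalizer is the value at the
    output time closest to ``t_norm`` (which must be inside the trajectory
    and positive).
    """
    t = np.asarray(traj.totals["t"])
    N_C = np.asarray(traj.totals["N_C"], dtype=float)
    if not (t[0] <= t_norm <= t[-1]):
        raise ValueError(f"normalization time {t_norm} outside trajectory [{t[0]}, {t[-1]}]")
    ref = N_C[int(np.argmin(np.abs(t - t_norm)))]
    if ref <= 0.0:
        raise ZeroDivisionError("complex count vanishes at the normalization time")
    return pd.Series(N_C / ref, index=pd.Index(t, name="t"), name="N_C_normalized")


def ring_profile(state, frame: KinematicsFrame) -> pd.DataFrame:
    """Radial profile of the complex density in the current configuration.

    Returns one row per meridian node ordered from the contact-disc center
    outward: current radial coordinate ``rho`` (µm), gap, referential
    complex density and the current-configuration density ``c_C / lambda_a``
    (what appears in a basal view of the cell).
    """
    # Traverse the meridian from the contact-disc center outward and up the
    # cap (mesh order reversed: theta = pi is the slide-facing pole), so the
    # basal profile comes first and rho is monotone across the contact disc.
    order = np.arange(frame.rho.size)[::-1]
    df = pd.DataFrame(
        {
            "rho": frame.rho,
            "g_N": frame.g_N,
            "c_C_ref": state.c_C,
            "c_C_current": state.c_C / frame.lambda_a,
            "contact": frame.contact,
        }
    )
    return df.iloc[order].reset_index(drop=True)


def apical_free_fraction(
    state,
    frame: KinematicsFrame,
    mesh: ReferenceSphereMesh,
    c_init: float,
    gap_min: float = 1.0,
    configuration: str = "referential",
) -> float:
    """Residual free-receptor density in the apical membrane, as a fraction.

    The apical membrane is taken as the nodes with gap above ``gap_min``
    (default 1 µm, safely away from the ligand-supplied rim).  The mean free
    receptor density there — area-weighted, referential by default — is
    divided by the initial uniform density ``c_init``.  With
    ``configuration='current'`` the density is first divided by the areal
    stretch, mimicking a per-image-area readout.
    """
    apical = frame.g_N > gap_min
    if not np.any(apical):
        raise ValueError(f"no nodes with gap above {gap_min} µm")
    w = mesh.weights[apical]
    c = state.c_R[apical]
    if configuration == "current":
        c = c / frame.lambda_a[apical]
    elif configuration != "referential":
        raise ValueError("configuration must be 'referential' or 'current'")
    return float((w @ c) / w.sum() / c_init)
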