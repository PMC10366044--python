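"""Short-range electrostatic binding-traction models (diagnostic).

Two published closed forms for the attractive normal traction exerted on the
membrane by receptor–ligand electrostatics, used to argue that such forces
are orders of magnitude too short-ranged and too weak to drive the spreading
of a 10 µm cell.  They never feed back into the kinematics here.

Sign convention: attraction toward the substrate is negative.  Tractions in
fN/µm², gaps in µm.

A note on units: the screened-Coulomb model is stated with an interaction
constant in fN·µm⁻⁵ combined with ``g**-5`` and an areal density, which does
not reduce to fN/µm² by inspection; the formula is treated as dimensionally
self-consistent in its source's unit system.  The inverse Debye length ``K``
is likewise taken as 1 µm⁻¹ (no unit is stated with it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TractionParamsGN",
    "TractionParamsExp",
    "traction_gn",
    "traction_exp",
    "traction_profile",
]


@dataclass(frozen=True)
class TractionParamsGN:
    """Screened-Coulomb (Debye) traction: interaction constant ``C``
    (fN·µm⁻⁵), inverse Debye length ``K`` (µm⁻¹), receptor–ligand density
    ``rho_rl`` (µm⁻²) and minimum approach distance ``h0`` (µm)."""

    C: float = 1.17e-7
    K: float = 1.0
    rho_rl: float = 1.0e5
    h0: float = 0.009

    def __post_init__(self) -> None:
        if min(self.C, self.K, self.rho_rl, self.h0) <= 0.0:
            raise ValueError("all screened-Coulomb parameters must be positive")


@dataclass(frozen=True)
class TractionParamsExp:
    """Exponential-decay traction: scale ``Q`` (fN/µm²) and decay length
    ``delta_p`` (µm)."""

    Q: float = 5.0e7
    delta_p: float = 0.13

    def __post_init__(self) -> None:
        if self.Q <= 0.0 or self.delta_p <= 0.0:
            raise ValueError("traction scale and decay length must be positive")


def traction_gn(g, p: TractionParamsGN = TractionParamsGN()):
    """Screened-Coulomb binding traction
    ``-C (Kg+1) [(Kg+1)^2 + 1] g^-5 exp(-2Kg) rho_rl``.

    Defined only above the minimum approach distance ``h0``; monotonically
    decaying in magnitude and vanishing at long range.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < p.h0):
        raise ValueError(f"gap below minimum approach distance h0={p.h0} µm")
    kg1 = p.K * g + 1.0
    t = -p.C * kg1 * (kg1**2 + 1.0) * g**-5 * np.exp(-2.0 * p.K * g) * p.rho_rl
    return t if t.ndim else float(t)


def traction_exp(g, p: TractionParamsExp = TractionParamsExp()):
    """Exponential binding traction ``-Q (g/delta_p) exp(-g/delta_p)``.

    Zero at contact, single interior extremum of magnitude ``Q/e`` at
    ``g = delta_p``, vanishing at long range.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0.0):
        raise ValueError("gap must be nonnegative")
    x = g / p.delta_p
    t = -p.Q * x * np.exp(-x)
    return t if t.ndim else float(t)


def traction_profile(
    g_grid,
    p_gn: TractionParamsGN = TractionParamsGN(),
    p_exp: TractionParamsExp = TractionParamsExp(),
) -> pd.DataFrame:
    """Tabulate both traction models over a gap grid.

    Gaps below the screened-Coulomb minimum approach distance get NaN in
    that column.  The ``ratio_exp_gn`` column reports the pointwise magnitude
    ratio of the exponential to the screened-Coulomb model — about four
    orders of magnitude over the physiological gap range.
    """
    g = np.asarray(g_grid, dtype=float)
    if np.any(g < 0.0):
        raise ValueError("gap grid must be nonnegative")
    t_gn = np.full_like(g, np.nan)
    ok = g >= p_gn.h0
    t_gn[ok] = traction_gn(g[ok], p_gn)
    t_exp = traction_exp(g, p_exp)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(t_exp) / np.abs(t_gn)
    return pd.DataFrame(
        {"g_N": g, "traction_gn": t_gn, "traction_exp": t_exp, "ratio_exp_gn": ratio}
    )
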