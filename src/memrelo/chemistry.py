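"""Receptor–ligand binding chemistry with instantaneous equilibrium closure.

The reaction R + L <-> C between a membrane receptor (R), a substrate-bound
ligand (L) and their complex (C) is assumed much faster than both membrane
transport and the mechanical deformation, so species are in local chemical
equilibrium at all times.  All concentrations are *referential*: molecules
per unit reference membrane area (µm⁻²), which integrate to molecule counts
without a Jacobian.

Three relations close the system at each membrane point:

* ligand bookkeeping ``c_L + c_C = S_L`` with the available-ligand density
  ``S_L = c_L^av exp(-g_N / ell_chem)`` set by the contact gap;
* receptor bookkeeping through the difference field ``c_D = c_R - c_L``;
* mass-action equilibrium ``c_C = c_R c_L / alpha`` with
  ``alpha = (c_R^max c_L^max / c_C^max) * lambda_a / K_eq``, where
  ``lambda_a`` is the areal stretch and ``K_eq = exp(-dG0 / (R T))``.

Eliminating ``c_L`` and ``c_C`` leaves a quadratic in ``c_R`` whose unique
nonnegative root is taken (base model).  The split model partitions the
receptors into a mobile (diffusing) and an immobile pool sharing the same
ligand bath; the per-node conserved totals ``c_m`` and ``c_i`` then reduce
the closure to a quadratic in the free-ligand density ``c_L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_GAS = 8.314462  # universal gas constant, J/(mol K)

__all__ = [
    "R_GAS",
    "ChemistryParams",
    "equilibrium_constant",
    "available_ligands",
    "alpha_coefficient",
    "solve_equilibrium_base",
    "solve_equilibrium_split",
    "mass_action_rate",
]


@dataclass(frozen=True)
class ChemistryParams:
    """Binding and transport parameters of the receptor–ligand system.

    Defaults are the calibrated values for VEGFR2 binding surface-adsorbed
    gremlin at 37 °C.  ``K_eq`` may be given directly or derived from the
    standard Gibbs free energy ``dG0`` (J/mol); if both are supplied they
    must agree to 0.1% relative.  ``cRmax``/``cCmax`` default to equal
    (their ratio is all that enters the equilibrium coefficient).

    Parameters
    ----------
    dG0 : float
        Standard Gibbs free energy of binding, J/mol.
    T : float
        Absolute temperature, K.
    K_eq : float or None
        Dimensionless invariant equilibrium constant.
    cLmax : float
        Ligand saturation limit, molecules/µm².
    cLav : float
        Maximum available-ligand density on the substrate, molecules/µm².
    ell_chem : float
        Chemical length scale of the gap-dependent ligand supply, µm.
    D_R : float
        Receptor diffusivity on the membrane, µm²/s.
    cRmax, cCmax : float or None
        Receptor/complex saturation limits; only their ratio matters and it
        defaults to one.
    kf, kb : float or None
        Forward/backward kinetic constants for the diagnostic finite-kinetics
        rate; the production path uses instantaneous equilibrium.
    """

    dG0: float = -32949.0
    T: float = 310.15
    K_eq: float | None = None
    cLmax: float = 16000.0
    cLav: float = 90.0
    ell_chem: float = 0.2
    D_R: float = 0.198
    cRmax: float | None = None
    cCmax: float | None = None
    kf: float | None = None
    kb: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0.0:
            raise ValueError("temperature must be positive")
        if self.cLmax <= 0.0 or self.cLav < 0.0 or self.ell_chem <= 0.0 or self.D_R < 0.0:
            raise ValueError("concentrations, length scale and diffusivity must be positive")
        if self.cLav > self.cLmax:
            raise ValueError("available ligand density cannot exceed the saturation limit")
        K_from_G = equilibrium_constant(self.dG0, self.T)
        if self.K_eq is None:
            object.__setattr__(self, "K_eq", K_from_G)
        elif abs(self.K_eq - K_from_G) > 1e-3 * abs(self.K_eq):
            raise ValueError(
                f"K_eq={self.K_eq} inconsistent with exp(-dG0/RT)={K_from_G:.2f} at T={self.T} K"
            )

    @property
    def saturation_ratio(self) -> float:
        """``cRmax * cLmax / cCmax`` entering the equilibrium coefficient."""
        if self.cRmax is None or self.cCmax is None:
            return self.cLmax
        return self.cRmax * self.cLmax / self.cCmax


def equilibrium_constant(dG0: float, T: float) -> float:
    """Invariant equilibrium constant ``exp(-dG0 / (R T))``."""
    if T <= 0.0:
        raise ValueError(f"temperature must be positive, got {T}")
    return float(np.exp(-dG0 / (R_GAS * T)))


def available_ligands(g_N, p: ChemistryParams):
    """Available-ligand density ``S_L = cLav * exp(-g_N / ell_chem)``.

    Maximal where the membrane touches the slide and negligible beyond a few
    chemical lengths; ``g_N`` may be a scalar or array (µm).
    """
    g_N = np.asarray(g_N, dtype=float)
    if np.any(g_N < 0.0):
        raise ValueError("gap must be nonnegative")
    out = p.cLav * np.exp(-g_N / p.ell_chem)
    return out if out.ndim else float(out)


def alpha_coefficient(lambda_a, p: ChemistryParams):
    """Equilibrium coefficient ``alpha = (cRmax cLmax / cCmax) lambda_a / K_eq``.

    The areal stretch ``lambda_a`` (``J |F^{-T} n_R|``) pulls the mass-action
    closure back to the reference configuration; larger stretch dilutes the
    current-configuration concentrations and weakens apparent binding.
    """
    lambda_a = np.asarray(lambda_a, dtype=float)
    if np.any(lambda_a <= 0.0):
        raise ValueError("areal stretch must be positive")
    out = p.saturation_ratio * lambda_a / p.K_eq
    return out if out.ndim else float(out)


def _clamp_roundoff(x: np.ndarray, scale, tol: float = 1e-12) -> np.ndarray:
    """Zero out negatives within round-off of 0; larger negatives are errors."""
    floor = -tol * np.maximum(1.0, scale)
    if np.any(x < floor):
        raise ArithmeticError(f"equilibrium produced negative concentration: min={np.min(x)}")
    return np.maximum(x, 0.0)


def solve_equilibrium_base(c_D, S_L, alpha):
    """Equilibrium concentrations ``(c_R, c_L, c_C)`` of the base model.

    Solves the quadratic
    ``c_R**2 + (alpha - c_D) c_R - alpha (S_L + c_D) = 0``
    for its unique nonnegative root (the product of the roots is
    ``-alpha (S_L + c_D) <= 0`` whenever the nodal receptor total
    ``S_L + c_D = c_R + c_C`` is nonnegative), then recovers
    ``c_L = c_R - c_D`` and ``c_C = S_L - c_L``.  Inputs may be scalars or
    arrays; round-off negatives are clamped at 1e-12 relative.
    """
    c_D = np.asarray(c_D, dtype=float)
    S_L = np.asarray(S_L, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    scalar = c_D.ndim == 0 and S_L.ndim == 0 and alpha.ndim == 0
    c_D, S_L, alpha = np.atleast_1d(c_D, S_L, alpha)
    if np.any(alpha <= 0.0):
        raise ValueError("alpha must be positive")
    if np.any(S_L < 0.0):
        raise ValueError("available-ligand density must be nonnegative")
    total = S_L + c_D  # nodal free-receptor + complex total
    if np.any(total < -1e-9 * np.maximum(1.0, np.abs(c_D))):
        raise ValueError("infeasible state: nodal receptor total S_L + c_D is negative")
    total = np.maximum(total, 0.0)

    b = alpha - c_D
    disc = np.sqrt(b * b + 4.0 * alpha * total)
    # Stable evaluation of the positive root on both branches of b.
    c_R = np.where(b > 0.0, 2.0 * alpha * total / (b + disc), 0.5 * (disc - b))
    c_L = c_R - c_D
    c_C = S_L - c_L
    scale = np.maximum(np.maximum(np.abs(c_D), S_L), np.maximum(alpha, 1.0))
    c_R = _clamp_roundoff(c_R, scale)
    c_L = _clamp_roundoff(c_L, scale)
    c_C = _clamp_roundoff(c_C, scale)
    if scalar:
        return float(c_R[0]), float(c_L[0]), float(c_C[0])
    return c_R, c_L, c_C


def solve_equilibrium_split(c_m, c_i, S_L, alpha):
    """Equilibrium of the mobile/immobile split model.

    ``c_m = c_R^m + c_C^m`` and ``c_i = c_R^i + c_C^i`` are the per-node
    conserved totals of the mobile and immobile receptor pools.  Both pools
    share the free-ligand bath, so eliminating the complexes through the
    closures ``c_C^x = c_R^x c_L / alpha`` yields a single scalar condition

        ``c_L * (1 + (c_m + c_i) / (alpha + c_L)) = S_L``

    whose left side increases monotonically in ``c_L``; expanding gives the
    quadratic ``c_L**2 + (alpha + c_m + c_i - S_L) c_L - alpha S_L = 0``
    solved in closed form for its nonnegative root.  Returns
    ``(c_R_m, c_R_i, c_L, c_C_m, c_C_i)``.
    """
    c_m = np.asarray(c_m, dtype=float)
    c_i = np.asarray(c_i, dtype=float)
    S_L = np.asarray(S_L, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    scalar = max(c_m.ndim, c_i.ndim, S_L.ndim, alpha.ndim) == 0
    c_m, c_i, S_L, alpha = np.atleast_1d(c_m, c_i, S_L, alpha)
    if np.any(alpha <= 0.0):
        raise ValueError("alpha must be positive")
    if np.any(c_m < 0.0) or np.any(c_i < 0.0) or np.any(S_L < 0.0):
        raise ValueError("pool totals and ligand density must be nonnegative")

    b = alpha + c_m + c_i - S_L
    disc = np.sqrt(b * b + 4.0 * alpha * S_L)
    c_L = np.where(b > 0.0, 2.0 * alpha * S_L / (b + disc), 0.5 * (disc - b))
    c_L = np.minimum(c_L, S_L)  # guard round-off overshoot of the bracket
    frac_free = alpha / (alpha + c_L)
    c_R_m = c_m * frac_free
    c_R_i = c_i * frac_free
    c_C_m = c_m - c_R_m
    c_C_i = c_i - c_R_i
    if scalar:
        return (float(c_R_m[0]), float(c_R_i[0]), float(c_L[0]),
                float(c_C_m[0]), float(c_C_i[0]))
    return c_R_m, c_R_i, c_L, c_C_m, c_C_i


def mass_action_rate(theta_R, theta_L, theta_C, kf: float, kb: float):
    """Net forward reaction rate by the saturation-aware law of mass action.

    ``w = kf * theta_L/(1-theta_L) * theta_R/(1-theta_R) - kb * theta_C/(1-theta_C)``
    with occupancy fractions ``theta_x = c_x / c_x^max`` in ``[0, 1)``.
    Diagnostic only: the solver replaces finite kinetics by the equilibrium
    closure, which this rate recovers as its zero set with
    ``kf / kb = K_eq``.
    """
    theta_R, theta_L, theta_C = (np.asarray(x, dtype=float) for x in (theta_R, theta_L, theta_C))
    if np.any((theta_R < 0) | (theta_R >= 1) | (theta_L < 0) | (theta_L >= 1)
              | (theta_C < 0) | (theta_C >= 1)):
        raise ValueError("occupancy fractions must lie in [0, 1)")
    w = (kf * (theta_L / (1.0 - theta_L)) * (theta_R / (1.0 - theta_R))
         - kb * theta_C / (1.0 - theta_C))
    return w if w.ndim else float(w)
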