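"""Surface reaction–diffusion solver on the reference membrane sphere.

The governing field is the difference ``c_D = c_R - c_L`` (base model) or the
conserved mobile-pool density ``c_m = c_R^m + c_C^m`` (split model), advanced
on the *reference* sphere with linear finite elements on the axisymmetric
meridian and the trapezoidal (Crank–Nicolson) rule in time:

    M (c_D^n - c_D^{n-1}) + (dt/2) K (c_R^n + c_R^{n-1})
                          + M (S_L^n - S_L^{n-1}) = 0 ,

with the instantaneous-equilibrium closure re-imposed node-wise after every
sub-step.  Because the closure makes ``c_R`` a nonlinear (but smooth,
monotone) function of ``c_D``, each sub-step solves the constrained update
by Newton iteration on the tridiagonal system; the Jacobian uses the exact
derivative of the equilibrium root.

The kinematics enter one-way: frames supply the gap (hence the available
ligands ``S_L``) and the areal stretch (hence the equilibrium coefficient
``alpha``), linearly interpolated in time across each mechanical step and
sub-incremented for the chemistry.

Mass bookkeeping: with the lumped mass built from the Voronoi zone weights
(the default), the scheme conserves the total receptor count
``sum_i w_i (c_R + c_C)_i`` to round-off, because the row sums of the mass
matrix coincide with the quadrature weights and ``K`` annihilates constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse

from .chemistry import (
    ChemistryParams,
    alpha_coefficient,
    available_ligands,
    solve_equilibrium_base,
    solve_equilibrium_split,
)
from .geometry import CapKinematics, KinematicsFrame, ReferenceSphereMesh, StagePlan

__all__ = [
    "SurfaceOperators",
    "FieldState",
    "Trajectory",
    "SimulationConfig",
    "assemble_operators",
    "initial_state",
    "step_base",
    "step_split",
    "run_simulation",
]

# Gauss-Legendre points/weights on [0, 1], 4 points (exact to degree 7).
_GP = 0.5 + 0.5 * np.array(
    [-0.8611363115940526, -0.3399810435848563, 0.3399810435848563, 0.8611363115940526]
)
_GW = 0.5 * np.array(
    [0.3478548451374538, 0.6521451548625461, 0.6521451548625461, 0.3478548451374538]
)


@dataclass(frozen=True)
class SurfaceOperators:
    """Mass and stiffness operators of the meridian finite-element space.

    ``M`` is the consistent mass matrix (reference-area inner product) and
    ``K`` the Dirichlet form of the projected surface gradient scaled by the
    receptor diffusivity; both are symmetric tridiagonal.  ``lumped`` holds
    the Voronoi zone weights, i.e. the diagonal of the lumped mass.
    """

    mesh: ReferenceSphereMesh
    D_R: float
    m_diag: np.ndarray
    m_off: np.ndarray
    k_diag: np.ndarray
    k_off: np.ndarray
    lumped: np.ndarray

    @property
    def M(self) -> scipy.sparse.csr_matrix:
        n = self.m_diag.size
        return scipy.sparse.diags(
            [self.m_off, self.m_diag, self.m_off], [-1, 0, 1], (n, n)
        ).tocsr()

    @property
    def K(self) -> scipy.sparse.csr_matrix:
        n = self.k_diag.size
        return scipy.sparse.diags(
            [self.k_off, self.k_diag, self.k_off], [-1, 0, 1], (n, n)
        ).tocsr()

    def apply_K(self, c: np.ndarray) -> np.ndarray:
        y = self.k_diag * c
        y[:-1] += self.k_off * c[1:]
        y[1:] += self.k_off * c[:-1]
        return y

    def apply_M(self, c: np.ndarray) -> np.ndarray:
        y = self.m_diag * c
        y[:-1] += self.m_off * c[1:]
        y[1:] += self.m_off * c[:-1]
        return y


def assemble_operators(mesh: ReferenceSphereMesh, D_R: float) -> SurfaceOperators:
    """Assemble mass and stiffness matrices on the axisymmetric meridian.

    One-dimensional linear elements with the surface-of-revolution measure
    ``2 pi r0^2 sin(theta) dtheta``.  Element stiffness integrals are exact;
    element mass integrals use 4-point Gauss quadrature except that the
    first diagonal entry is recovered from the exact zone area, which makes
    the row sums of ``M`` telescope exactly to the sphere area.
    """
    if D_R < 0.0:
        raise ValueError("diffusivity must be nonnegative")
    th = mesh.theta
    L = np.diff(th)
    if np.any(L <= 0.0):
        raise ValueError("degenerate mesh: non-increasing meridian angles")
    r0 = mesh.r0
    dcos = np.cos(th[:-1]) - np.cos(th[1:])  # exact zone integral of sin(theta)

    # Stiffness: d(phi)/ds = +-1/(r0 L); measure contributes 2 pi r0^2 dcos.
    ke = 2.0 * np.pi * D_R * dcos / L**2
    n = th.size
    k_diag = np.zeros(n)
    k_diag[:-1] += ke
    k_diag[1:] += ke
    k_off = -ke

    # Mass: I12 = int (1-xi) xi sin(theta) L dxi etc., Gauss on each element.
    thq = th[:-1, None] + L[:, None] * _GP[None, :]
    sq = np.sin(thq)
    I12 = L * np.einsum("q,eq->e", _GW * _GP * (1.0 - _GP), sq)
    I22 = L * np.einsum("q,eq->e", _GW * _GP**2, sq)
    I11 = dcos - 2.0 * I12 - I22  # telescoping: row sums stay exact
    coef = 2.0 * np.pi * r0**2
    m_diag = np.zeros(n)
    m_diag[:-1] += coef * I11
    m_diag[1:] += coef * I22
    m_off = coef * I12

    return SurfaceOperators(
        mesh=mesh,
        D_R=float(D_R),
        m_diag=m_diag,
        m_off=m_off,
        k_diag=k_diag,
        k_off=k_off,
        lumped=mesh.weights.copy(),
    )


@dataclass
class FieldState:
    """Referential nodal concentrations at one time (molecules/µm²).

    For the base model ``c_R``/``c_L``/``c_C`` are the free-receptor,
    free-ligand and complex densities and ``c_D = c_R - c_L`` the evolved
    difference field.  The split model adds the mobile/immobile components
    and their per-node conserved totals ``c_m``/``c_i``; then ``c_R`` and
    ``c_C`` hold the pooled (mobile + immobile) free and complexed densities.
    """

    model: str
    t: float
    c_R: np.ndarray
    c_L: np.ndarray
    c_C: np.ndarray
    c_D: np.ndarray
    S_L: np.ndarray
    alpha: np.ndarray
    c_m: np.ndarray | None = None
    c_i: np.ndarray | None = None
    c_R_m: np.ndarray | None = None
    c_R_i: np.ndarray | None = None
    c_C_m: np.ndarray | None = None
    c_C_i: np.ndarray | None = None

    def copy(self) -> "FieldState":
        kw = {}
        for name in ("c_R", "c_L", "c_C", "c_D", "S_L", "alpha",
                     "c_m", "c_i", "c_R_m", "c_R_i", "c_C_m", "c_C_i"):
            v = getattr(self, name)
            kw[name] = None if v is None else v.copy()
        return FieldState(model=self.model, t=self.t, **kw)


@dataclass
class Trajectory:
    """Output of a simulation run: totals at the output cadence plus snapshots."""

    times: np.ndarray
    totals: pd.DataFrame
    snapshots: list[tuple[float, FieldState, KinematicsFrame]]
    mesh: ReferenceSphereMesh
    config: "SimulationConfig"


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a run.

    The defaults are the calibrated study conditions: 24000 receptors on a
    10 µm cell, three stages to 7200 s, contact radius growing to 3.35 µm
    then 19.8 µm, and a 23% immobile fraction for the split variant.  The
    ``seed`` field is reserved for future stochastic extensions; the solver
    is fully deterministic.
    """

    model: str = "base"
    n_nodes: int = 200
    r0: float = 10.0
    N_total: float = 24000.0
    immobile_fraction: float = 0.23
    chemistry: ChemistryParams = field(default_factory=ChemistryParams)
    plan: StagePlan = field(default_factory=StagePlan)
    a_attach: float = 3.35
    a_final: float = 19.8
    output_every: float = 30.0
    mass: str = "lumped"
    store_fields: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("base", "split"):
            raise ValueError(f"model must be 'base' or 'split', got {self.model!r}")
        if not 0.0 <= self.immobile_fraction < 1.0:
            raise ValueError("immobile fraction must lie in [0, 1)")
        if self.mass not in ("lumped", "consistent"):
            raise ValueError("mass must be 'lumped' or 'consistent'")


def initial_state(
    mesh: ReferenceSphereMesh,
    p: ChemistryParams,
    frame0: KinematicsFrame,
    model: str = "base",
    N_total: float = 24000.0,
    immobile_fraction: float = 0.23,
) -> FieldState:
    """Uniform receptor distribution equilibrated against the initial supply.

    Receptors start homogeneously distributed (``N_total`` over the sphere
    area) with zero ligands and complexes; the instantaneous-equilibrium
    closure is then applied with the available ligands of the initial frame,
    which only affects the tangent node where the gap already vanishes.
    """
    c0 = N_total / mesh.total_area
    S0 = available_ligands(frame0.g_N, p)
    a0 = alpha_coefficient(frame0.lambda_a, p)
    if model == "base":
        c_D = np.full(mesh.n_nodes, c0) - S0
        c_R, c_L, c_C = solve_equilibrium_base(c_D, S0, a0)
        return FieldState(model="base", t=frame0.t, c_R=c_R, c_L=c_L, c_C=c_C,
                          c_D=c_D, S_L=S0, alpha=a0)
    if model == "split":
        c_i = np.full(mesh.n_nodes, immobile_fraction * c0)
        c_m = np.full(mesh.n_nodes, (1.0 - immobile_fraction) * c0)
        c_R_m, c_R_i, c_L, c_C_m, c_C_i = solve_equilibrium_split(c_m, c_i, S0, a0)
        return FieldState(
            model="split", t=frame0.t, c_R=c_R_m + c_R_i, c_L=c_L, c_C=c_C_m + c_C_i,
            c_D=c_R_m + c_R_i - c_L, S_L=S0, alpha=a0,
            c_m=c_m, c_i=c_i, c_R_m=c_R_m, c_R_i=c_R_i, c_C_m=c_C_m, c_C_i=c_C_i,
        )
    raise ValueError(f"unknown model {model!r}")


def _mass_arrays(ops: SurfaceOperators, mass: str):
    """(diag, off) arrays of the selected mass matrix; off is None if lumped."""
    if mass == "lumped":
        return ops.lumped, None
    if mass == "consistent":
        return ops.m_diag, ops.m_off
    raise ValueError(f"mass must be 'lumped' or 'consistent', got {mass!r}")


def _solve_tridiag(diag, off_l, off_u, rhs):
    n = diag.size
    ab = np.zeros((3, n))
    ab[0, 1:] = off_u
    ab[1] = diag
    ab[2, :-1] = off_l
    return scipy.linalg.solve_banded((1, 1), ab, rhs, check_finite=False)


def _dcR_dcD(c_R, c_L, alpha):
    """Derivative of the base equilibrium root with respect to ``c_D``."""
    return (c_R + alpha) / (c_R + c_L + alpha)


def _newton_substep(c_prev, cR_prev, rhs_extra, S1, a1, dtc, ops, mass,
                    closure, dclosure, tol, max_iter, guess=None):
    """Advance one chemo sub-step of M dc + (dtc/2) K (cR + cR_prev) + rhs = 0.

    ``closure(c)`` maps the evolved field to the diffusing free density and
    the full equilibrium tuple; ``dclosure`` gives its derivative for the
    Jacobian.  ``guess`` seeds the iteration (e.g. an extrapolation from the
    previous sub-step).  Returns the new evolved field and closure output.
    """
    m_diag, m_off = _mass_arrays(ops, mass)
    c = c_prev.copy() if guess is None else guess.copy()
    cR, out = closure(c)
    half = 0.5 * dtc
    KcR_prev = ops.apply_K(cR_prev)
    scale = max(1.0, float(np.max(np.abs(c_prev))))
    for it in range(max_iter):
        # Residual of the fully discrete sub-step equation.
        dc = c - c_prev
        if m_off is None:
            res = m_diag * (dc + rhs_extra)
        else:
            y = dc + rhs_extra
            res = m_diag * y
            res[:-1] += m_off * y[1:]
            res[1:] += m_off * y[:-1]
        res += half * (ops.apply_K(cR) + KcR_prev)
        d = dclosure(c, out)
        j_diag = m_diag + half * ops.k_diag * d
        j_up = half * ops.k_off * d[1:]
        j_lo = half * ops.k_off * d[:-1]
        if m_off is not None:
            j_up = j_up + m_off
            j_lo = j_lo + m_off
        delta = _solve_tridiag(j_diag, j_lo, j_up, res)
        c -= delta
        cR, out = closure(c)
        if float(np.max(np.abs(delta))) <= tol * scale:
            return c, cR, out
    raise RuntimeError(
        f"equilibrium-constrained sub-step did not converge in {max_iter} Newton "
        f"iterations (last update {float(np.max(np.abs(delta))):.3e})"
    )


def step_base(
    state: FieldState,
    frame_prev: KinematicsFrame,
    frame_next: KinematicsFrame,
    dt: float,
    ops: SurfaceOperators,
    p: ChemistryParams,
    substeps: int = 1,
    mass: str = "lumped",
    tol: float = 1e-10,
    max_iter: int = 50,
) -> FieldState:
    """One mechanical step of the base model with chemo sub-incrementation.

    The available ligands and the equilibrium coefficient are interpolated
    linearly in time between the two frames; the difference field ``c_D`` is
    advanced by the trapezoidal rule over ``substeps`` equal sub-steps, the
    nodal closure being re-solved after each.
    """
    S_a = available_ligands(frame_prev.g_N, p)
    S_b = available_ligands(frame_next.g_N, p)
    al_a = alpha_coefficient(frame_prev.lambda_a, p)
    al_b = alpha_coefficient(frame_next.lambda_a, p)
    c_D = state.c_D.copy()
    c_R = state.c_R.copy()
    dtc = dt / substeps
    out = (state.c_R, state.c_L, state.c_C)
    S1 = S_a
    a1 = al_a
    dc_last = None
    for k in range(1, substeps + 1):
        tau0, tau1 = (k - 1) / substeps, k / substeps
        S0 = S_a + (S_b - S_a) * tau0
        S1 = S_a + (S_b - S_a) * tau1
        a1 = al_a + (al_b - al_a) * tau1

        def closure(c, S=S1, a=a1):
            cR, cL, cC = solve_equilibrium_base(c, S, a)
            return cR, (cR, cL, cC)

        def dclosure(c, o, a=a1):
            return _dcR_dcD(o[0], o[1], a)

        guess = None if dc_last is None else c_D + dc_last
        c_D_old = c_D
        c_D, c_R, out = _newton_substep(
            c_D, c_R, S1 - S0, S1, a1, dtc, ops, mass, closure, dclosure,
            tol, max_iter, guess=guess,
        )
        dc_last = c_D - c_D_old
    c_R, c_L, c_C = out
    return FieldState(model="base", t=frame_next.t, c_R=c_R, c_L=c_L, c_C=c_C,
                      c_D=c_D, S_L=S1, alpha=np.broadcast_to(a1, c_R.shape).copy())


def step_split(
    state: FieldState,
    frame_prev: KinematicsFrame,
    frame_next: KinematicsFrame,
    dt: float,
    ops: SurfaceOperators,
    p: ChemistryParams,
    substeps: int = 1,
    mass: str = "lumped",
    tol: float = 1e-10,
    max_iter: int = 50,
) -> FieldState:
    """One mechanical step of the mobile/immobile split model.

    The immobile per-node total ``c_i`` is constant in time (no flux, no
    receptor supply); the mobile total ``c_m`` diffuses through its free
    fraction only.  The ligand field follows from the shared-bath closure.
    """
    S_a = available_ligands(frame_prev.g_N, p)
    S_b = available_ligands(frame_next.g_N, p)
    al_a = alpha_coefficient(frame_prev.lambda_a, p)
    al_b = alpha_coefficient(frame_next.lambda_a, p)
    c_m = state.c_m.copy()
    c_i = state.c_i
    c_R_m = state.c_R_m.copy()
    dtc = dt / substeps
    out = (state.c_R_m, state.c_R_i, state.c_L, state.c_C_m, state.c_C_i)
    a1 = al_a
    dc_last = None
    for k in range(1, substeps + 1):
        tau1 = k / substeps
        S1 = S_a + (S_b - S_a) * tau1
        a1 = al_a + (al_b - al_a) * tau1

        def closure(c, S=S1, a=a1):
            res = solve_equilibrium_split(c, c_i, S, a)
            return res[0], res

        def dclosure(c, o, S=S1, a=a1):
            # c_L root of c_L^2 + (a + c + c_i - S) c_L - a S = 0.
            cL = o[2]
            root_disc = 2.0 * cL + a + c + c_i - S
            dcL = np.where(root_disc > 0.0, -cL / np.maximum(root_disc, 1e-300), 0.0)
            frac = a / (a + cL)
            return frac - c * a / (a + cL) ** 2 * dcL

        zero = np.zeros_like(c_m)
        guess = None if dc_last is None else c_m + dc_last
        c_m_old = c_m
        c_m, c_R_m, out = _newton_substep(
            c_m, c_R_m, zero, S1, a1, dtc, ops, mass, closure, dclosure,
            tol, max_iter, guess=guess,
        )
        dc_last = c_m - c_m_old
    c_R_m, c_R_i, c_L, c_C_m, c_C_i = out
    return FieldState(
        model="split", t=frame_next.t, c_R=c_R_m + c_R_i, c_L=c_L, c_C=c_C_m + c_C_i,
        c_D=c_R_m + c_R_i - c_L, S_L=S_a + (S_b - S_a), alpha=np.broadcast_to(a1, c_L.shape).copy(),
        c_m=c_m, c_i=c_i.copy(), c_R_m=c_R_m, c_R_i=c_R_i, c_C_m=c_C_m, c_C_i=c_C_i,
    )


def run_simulation(
    config: SimulationConfig,
    kinematics: Callable[[float], KinematicsFrame] | None = None,
    t_stop: float | None = None,
) -> Trajectory:
    """Execute the staggered three-stage simulation.

    Per stage: the kinematics frame is updated at the mechanical step, then
    the chemo-transport problem is sub-incremented across the step (strictly
    one-way coupling).  Totals (and field snapshots, if requested) are
    recorded at the output cadence and at stage boundaries.  ``t_stop``
    truncates the run early (e.g. attachment stage only); it must align with
    a mechanical step of its stage.
    """
    from .observables import integrate_totals  # deferred: avoids module cycle

    mesh = build_mesh_for(config)
    ops = assemble_operators(mesh, config.chemistry.D_R)
    plan = config.plan
    if kinematics is None:
        kinematics = CapKinematics(mesh, plan, config.a_attach, config.a_final)
    stepper = step_base if config.model == "base" else step_split

    frame = kinematics(0.0)
    state = initial_state(mesh, config.chemistry, frame, config.model,
                          config.N_total, config.immobile_fraction)

    records: list[dict] = []
    snapshots: list[tuple[float, FieldState, KinematicsFrame]] = []

    def record(t: float, st: FieldState, fr: KinematicsFrame) -> None:
        tot = integrate_totals(st, mesh)
        records.append({
            "t": t,
            "N_R_free": tot.N_R_free,
            "N_C": tot.N_C,
            "N_L_free": tot.N_L_free,
            "N_L_available": tot.N_L_available,
            "contact_area": fr.cap.disc_area,
        })
        if config.store_fields:
            snapshots.append((t, st.copy(), fr))

    record(0.0, state, frame)
    next_out = config.output_every
    bounds = [0.0, plan.t_attach, plan.t_transloc, plan.t_end]
    if t_stop is None:
        t_stop = plan.t_end
    t = 0.0
    for stage in range(3):
        t0, t1 = bounds[stage], min(bounds[stage + 1], t_stop)
        if t1 <= t0:
            break
        dt = plan.dt_stage[stage]
        n_steps = int(round((t1 - t0) / dt))
        if abs(t0 + n_steps * dt - t1) > 1e-9 * max(1.0, t1):
            raise ValueError(
                f"stage {stage} duration {t1 - t0} is not a multiple of dt={dt}"
            )
        substeps = plan.substeps_by_stage[stage]
        for k in range(1, n_steps + 1):
            t_new = t0 + k * dt
            frame_next = kinematics(t_new)
            state = stepper(state, frame, frame_next, dt, ops, config.chemistry,
                            substeps, config.mass)
            frame = frame_next
            t = t_new
            if t + 1e-9 >= next_out or k == n_steps:
                record(t, state, frame)
                while next_out <= t + 1e-9:
                    next_out += config.output_every
    totals = pd.DataFrame.from_records(records).drop_duplicates(subset="t")
    return Trajectory(times=totals["t"].to_numpy(), totals=totals.reset_index(drop=True),
                      snapshots=snapshots, mesh=mesh, config=config)


def build_mesh_for(config: SimulationConfig) -> ReferenceSphereMesh:
    from .geometry import build_meridian_mesh

    return build_meridian_mesh(config.r0, config.n_nodes)
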