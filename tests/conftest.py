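"""Shared fixtures: meshes, parameter sets and the expensive reference runs.

The three simulation fixtures (attachment stage, full split run, full base
run with reduced ligand availability) are session-scoped because several
test modules interrogate the same trajectories.  The explicit-Euler oracle
re-integrates the attachment problem with first-order time stepping at a
1000-fold smaller step than the mechanical one, independently of the
production trapezoidal scheme.
"""

from __future__ import annotations

import numpy as np
import pytest

import memrelo as mr
from memrelo.chemistry import alpha_coefficient, available_ligands, solve_equilibrium_base
from memrelo.transport import assemble_operators

C_INIT = 24000.0 / (4.0 * np.pi * 100.0)  # initial receptor density, 1/µm²


@pytest.fixture(scope="session")
def mesh200():
    return mr.build_meridian_mesh(10.0, 200)


@pytest.fixture(scope="session")
def chem():
    return mr.ChemistryParams()


@pytest.fixture(scope="session")
def attachment_run():
    """Base model over the attachment stage: 200 nodes, substep factor 10."""
    cfg = mr.SimulationConfig(
        model="base", n_nodes=200, plan=mr.StagePlan(substeps=10),
        output_every=30.0, store_fields=True,
    )
    return mr.run_simulation(cfg, t_stop=300.0)


@pytest.fixture(scope="session")
def split_full_run():
    """Split model over the full 7200 s schedule, 200 nodes.

    Sub-incrementation 10 during the kinematically active stages and 1 in
    the frozen diffusion stage (its chemo step of 0.05 s is already far
    below the transport time scale; halving/doubling checks show <1e-8
    sensitivity).
    """
    cfg = mr.SimulationConfig(
        model="split", n_nodes=200, plan=mr.StagePlan(substeps=(10, 10, 1)),
        output_every=150.0, store_fields=True,
    )
    return mr.run_simulation(cfg)


@pytest.fixture(scope="session")
def base60_full_run():
    """Base model, available ligands reduced to 60 /µm², full schedule."""
    cfg = mr.SimulationConfig(
        model="base", n_nodes=200, chemistry=mr.ChemistryParams(cLav=60.0),
        plan=mr.StagePlan(substeps=(10, 10, 1)), output_every=600.0,
        store_fields=False,
    )
    return mr.run_simulation(cfg)


@pytest.fixture(scope="session")
def oracle_comparison():
    """Total complexes after the attachment stage on a 30-node mesh, computed
    twice: by the production trapezoidal scheme and by a brute-force explicit
    Euler integration with a 1000x smaller time step (5e-4 s).
    """
    mesh = mr.build_meridian_mesh(10.0, 30)
    ops = assemble_operators(mesh, 0.198)
    p = mr.ChemistryParams()
    plan = mr.StagePlan(substeps=10)
    kin = mr.CapKinematics(mesh, plan)

    cfg = mr.SimulationConfig(n_nodes=30, plan=plan, output_every=300.0,
                              store_fields=False)
    traj = mr.run_simulation(cfg, t_stop=300.0)
    N_C_trapezoid = float(traj.totals.iloc[-1]["N_C"])

    # Independent first-order reference: forward Euler on the lumped system
    # dc_D = -dS - dt * W^-1 K c_R, closure re-solved after every step.
    dt = 5e-4
    w_inv = 1.0 / mesh.weights
    frame0 = kin(0.0)
    S_prev = available_ligands(frame0.g_N, p)
    c_D = np.full(30, C_INIT) - S_prev
    c_R, _, c_C = solve_equilibrium_base(c_D, S_prev, alpha_coefficient(frame0.lambda_a, p))
    mech_t0 = 0.0
    f_prev, f_next = kin(0.0), kin(0.5)
    S_a, S_b = available_ligands(f_prev.g_N, p), available_ligands(f_next.g_N, p)
    a_a, a_b = alpha_coefficient(f_prev.lambda_a, p), alpha_coefficient(f_next.lambda_a, p)
    n_steps = int(round(300.0 / dt))
    for k in range(n_steps):
        t_new = (k + 1) * dt
        if t_new > mech_t0 + 0.5 + 1e-12:
            mech_t0 += 0.5
            f_prev, f_next = f_next, kin(mech_t0 + 0.5)
            S_a, S_b = S_b, available_ligands(f_next.g_N, p)
            a_a, a_b = a_b, alpha_coefficient(f_next.lambda_a, p)
        tau = (t_new - mech_t0) / 0.5
        S1 = S_a + (S_b - S_a) * tau
        a1 = a_a + (a_b - a_a) * tau
        c_D = c_D - (S1 - S_prev) - dt * w_inv * ops.apply_K(c_R)
        c_R, _, c_C = solve_equilibrium_base(c_D, S1, a1)
        S_prev = S1
    N_C_euler = float(mesh.weights @ c_C)
    return N_C_trapezoid, N_C_euler


@pytest.fixture(scope="session")
def harmonic_decay():
    """Amplitude of a cos(theta) perturbation after 100 s of pure diffusion
    on the fixed reference sphere (no ligands), vs the closed-form
    Laplace–Beltrami decay exp(-2 D t / r0^2) of the degree-1 zonal mode.
    """
    from memrelo.transport import FieldState, step_base

    n = 200
    mesh = mr.build_meridian_mesh(10.0, n)
    ops = assemble_operators(mesh, 0.198)
    p = mr.ChemistryParams(cLav=0.0)
    kin = mr.CapKinematics(mesh, mr.StagePlan())
    frame = kin(0.0)
    c0 = C_INIT * (1.0 + 0.1 * np.cos(mesh.theta))
    zeros = np.zeros(n)
    state = FieldState(model="base", t=0.0, c_R=c0.copy(), c_L=zeros.copy(),
                       c_C=zeros.copy(), c_D=c0.copy(), S_L=zeros.copy(),
                       alpha=np.full(n, 0.045))
    for _ in range(200):
        state = step_base(state, frame, frame, 0.5, ops, p, substeps=1)
    w, ct = mesh.weights, np.cos(mesh.theta)
    amplitude = float((w * ct) @ state.c_R / ((w * ct) @ ct))
    expected = C_INIT * 0.1 * np.exp(-2.0 * 0.198 * 100.0 / 100.0)
    return amplitude, expected
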