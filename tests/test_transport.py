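"""Finite-element operators, time stepping, conservation and convergence."""

import numpy as np
import pytest
import scipy.linalg

import memrelo as mr
from memrelo.transport import assemble_operators, initial_state, step_base, step_split


class TestSurfaceOperators:
    def test_constants_in_stiffness_kernel(self):
        mesh = mr.build_meridian_mesh(10.0, 120)
        ops = assemble_operators(mesh, 0.198)
        assert np.max(np.abs(ops.apply_K(np.ones(120)))) < 1e-12

    def test_mass_integrates_to_reference_area(self):
        mesh = mr.build_meridian_mesh(10.0, 120)
        ops = assemble_operators(mesh, 0.198)
        one = np.ones(120)
        assert float(one @ ops.apply_M(one)) == pytest.approx(1256.64, abs=5e-3)
        assert float(one @ ops.apply_M(one)) == pytest.approx(mesh.total_area, rel=1e-10)

    def test_symmetry_and_definiteness(self):
        mesh = mr.build_meridian_mesh(10.0, 60)
        ops = assemble_operators(mesh, 0.198)
        M, K = ops.M.toarray(), ops.K.toarray()
        assert np.allclose(M, M.T) and np.allclose(K, K.T)
        assert np.min(scipy.linalg.eigvalsh(M)) > 0.0
        assert np.min(scipy.linalg.eigvalsh(K)) > -1e-12

    @pytest.mark.parametrize("n", [50, 100, 200])
    def test_degree_one_eigenvalue_of_sphere_laplacian(self, n):
        # smallest nonzero generalized eigenvalue -> D l(l+1)/r0^2, l=1
        mesh = mr.build_meridian_mesh(10.0, n)
        ops = assemble_operators(mesh, 0.198)
        ev = scipy.linalg.eigh(ops.K.toarray(), ops.M.toarray(), eigvals_only=True)
        lam1 = np.sort(ev)[1]
        assert lam1 == pytest.approx(2.0 * 0.198 / 100.0, rel=5e-3)


class TestStepBase:
    def setup_method(self):
        self.mesh = mr.build_meridian_mesh(10.0, 80)
        self.ops = assemble_operators(self.mesh, 0.198)
        self.kin = mr.CapKinematics(self.mesh, mr.StagePlan())

    def test_uniform_equilibrium_is_stationary(self):
        p = mr.ChemistryParams(cLav=0.0)
        frame = self.kin(0.0)
        state = initial_state(self.mesh, p, frame)
        new = step_base(state, frame, frame, 0.5, self.ops, p, substeps=4)
        assert np.max(np.abs(new.c_R - state.c_R)) < 1e-12

    def test_step_conserves_receptors(self, chem):
        frame = self.kin(0.0)
        state = initial_state(self.mesh, chem, frame)
        N0 = self.mesh.weights @ (state.c_R + state.c_C)
        t = 0.0
        for _ in range(40):
            nxt = self.kin(t + 0.5)
            state = step_base(state, frame, nxt, 0.5, self.ops, chem, substeps=5)
            frame, t = nxt, t + 0.5
        N1 = self.mesh.weights @ (state.c_R + state.c_C)
        assert N1 == pytest.approx(N0, rel=1e-12)

    def test_ligand_bookkeeping_after_steps(self, chem):
        frame = self.kin(0.0)
        state = initial_state(self.mesh, chem, frame)
        t = 0.0
        for _ in range(20):
            nxt = self.kin(t + 0.5)
            state = step_base(state, frame, nxt, 0.5, self.ops, chem, substeps=5)
            frame, t = nxt, t + 0.5
        assert np.max(np.abs(state.c_L + state.c_C - state.S_L)) < 1e-9

    def test_consistent_mass_reproduces_closed_form_decay(self):
        """The consistent-mass stepping path is exercised on smooth data,
        where it must match the Laplace–Beltrami decay rate; at the sharp
        ligand-supply front the positivity-preserving lumped form is the
        production path."""
        from memrelo.transport import FieldState

        n = 200
        mesh = mr.build_meridian_mesh(10.0, n)
        ops = assemble_operators(mesh, 0.198)
        p = mr.ChemistryParams(cLav=0.0)
        frame = mr.CapKinematics(mesh, mr.StagePlan())(0.0)
        c0 = 19.1 * (1.0 + 0.1 * np.cos(mesh.theta))
        z = np.zeros(n)
        state = FieldState(model="base", t=0.0, c_R=c0.copy(), c_L=z.copy(),
                           c_C=z.copy(), c_D=c0.copy(), S_L=z.copy(),
                           alpha=np.full(n, 0.045))
        for _ in range(100):
            state = step_base(state, frame, frame, 0.5, ops, p, substeps=1,
                              mass="consistent")
        w, ct = mesh.weights, np.cos(mesh.theta)
        amp = float((w * ct) @ state.c_R / ((w * ct) @ ct))
        assert amp == pytest.approx(1.91 * np.exp(-0.198), rel=1e-3)


class TestStepSplit:
    def setup_method(self):
        self.mesh = mr.build_meridian_mesh(10.0, 80)
        self.ops = assemble_operators(self.mesh, 0.198)
        self.kin = mr.CapKinematics(self.mesh, mr.StagePlan())

    def test_zero_immobile_fraction_reproduces_base_model(self, chem):
        frame = self.kin(0.0)
        sb = initial_state(self.mesh, chem, frame, "base")
        ss = initial_state(self.mesh, chem, frame, "split", immobile_fraction=0.0)
        t = 0.0
        fr = frame
        for _ in range(30):
            nxt = self.kin(t + 0.5)
            sb = step_base(sb, fr, nxt, 0.5, self.ops, chem, substeps=5)
            ss = step_split(ss, fr, nxt, 0.5, self.ops, chem, substeps=5)
            fr, t = nxt, t + 0.5
        assert np.max(np.abs(sb.c_R - ss.c_R)) < 1e-10
        assert np.max(np.abs(sb.c_C - ss.c_C)) < 1e-10

    def test_immobile_nodal_totals_constant(self, chem):
        frame = self.kin(0.0)
        ss = initial_state(self.mesh, chem, frame, "split")
        ci0 = (ss.c_R_i + ss.c_C_i).copy()
        t = 0.0
        fr = frame
        for _ in range(30):
            nxt = self.kin(t + 0.5)
            ss = step_split(ss, fr, nxt, 0.5, self.ops, chem, substeps=5)
            fr, t = nxt, t + 0.5
        assert np.max(np.abs(ss.c_R_i + ss.c_C_i - ci0)) < 1e-10


class TestRunSimulation:
    def test_zero_ligand_run_is_constant(self):
        cfg = mr.SimulationConfig(
            n_nodes=50, chemistry=mr.ChemistryParams(cLav=0.0),
            plan=mr.StagePlan(substeps=2), output_every=300.0,
        )
        traj = mr.run_simulation(cfg, t_stop=600.0)
        first, last = traj.snapshots[0][1], traj.snapshots[-1][1]
        assert np.array_equal(first.c_R, last.c_R)
        assert np.max(last.c_C) == 0.0

    def test_total_receptor_count_constant(self, attachment_run):
        tot = attachment_run.totals
        N = tot["N_R_free"] + tot["N_C"]
        assert np.max(np.abs(N / 24000.0 - 1.0)) < 1e-6

    def test_attachment_complexes_grow_monotonically(self, attachment_run):
        assert np.all(np.diff(attachment_run.totals["N_C"]) >= 0.0)

    def test_misaligned_stop_time_rejected(self):
        cfg = mr.SimulationConfig(n_nodes=50, plan=mr.StagePlan(substeps=1))
        with pytest.raises(ValueError):
            mr.run_simulation(cfg, t_stop=100.3)


class TestSchemeAccuracy:
    def test_harmonic_perturbation_decays_at_laplace_beltrami_rate(self, harmonic_decay):
        amplitude, expected = harmonic_decay
        assert amplitude == pytest.approx(expected, rel=1e-2)

    def test_trapezoidal_matches_explicit_euler_oracle(self, oracle_comparison):
        N_C_cn, N_C_euler = oracle_comparison
        assert N_C_cn == pytest.approx(N_C_euler, rel=5e-3)

    def test_time_step_refinement_stability(self):
        """Halving all mechanical steps while doubling the sub-incrementation
        changes the 1800 s complex total by far less than 0.5%."""

        def complexes(dt_scale, sub_scale):
            plan = mr.StagePlan(
                t_end=1800.0,
                dt_stage=(0.5 * dt_scale, 0.1 * dt_scale, 0.05 * dt_scale),
                substeps=(10 * sub_scale, 10 * sub_scale, 1 * sub_scale),
            )
            cfg = mr.SimulationConfig(n_nodes=60, plan=plan, store_fields=False,
                                      output_every=1800.0)
            return mr.run_simulation(cfg).totals.iloc[-1]["N_C"]

        coarse = complexes(1.0, 1)
        fine = complexes(0.5, 2)
        assert coarse == pytest.approx(fine, rel=5e-3)
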