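"""Equilibrium constant, ligand supply, and the equilibrium closures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import memrelo as mr
from memrelo.chemistry import R_GAS


class TestEquilibriumConstant:
    def test_reported_value_recovered_at_body_temperature(self):
        # exp(-dG0 / (R * 310.15 K)) must reproduce the published constant
        assert mr.equilibrium_constant(-32949.0, 310.15) == pytest.approx(
            354058.32, rel=5e-4)

    def test_zero_energy_gives_unity(self):
        assert mr.equilibrium_constant(0.0, 300.0) == 1.0

    def test_inverse_identity(self):
        T = 310.15
        assert mr.equilibrium_constant(-R_GAS * T * np.log(2.0), T) == pytest.approx(2.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            mr.equilibrium_constant(-1000.0, 0.0)

    def test_params_reject_inconsistent_keq(self):
        with pytest.raises(ValueError):
            mr.ChemistryParams(K_eq=300000.0)
        p = mr.ChemistryParams(K_eq=354058.32)
        assert p.K_eq == 354058.32


class TestAvailableLigands:
    def setup_method(self):
        self.p = mr.ChemistryParams()

    def test_contact_gives_maximum_availability(self):
        assert mr.available_ligands(0.0, self.p) == pytest.approx(90.0)

    def test_one_chemical_length_gives_factor_e(self):
        assert mr.available_ligands(0.2, self.p) == pytest.approx(90.0 / np.e, rel=1e-12)

    def test_long_range_vanishes(self):
        assert mr.available_ligands(50.0, self.p) < 1e-100

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            mr.available_ligands(-0.1, self.p)


class TestAlphaCoefficient:
    def setup_method(self):
        self.p = mr.ChemistryParams()

    def test_table_values(self):
        assert mr.alpha_coefficient(1.0, self.p) == pytest.approx(
            16000.0 / 354058.32, rel=2e-6)

    def test_proportional_to_stretch(self):
        a1 = mr.alpha_coefficient(1.0, self.p)
        assert mr.alpha_coefficient(2.0, self.p) == pytest.approx(2.0 * a1, rel=1e-14)

    def test_strong_binding_limit(self):
        p = mr.ChemistryParams(dG0=-2e5)  # enormous K_eq
        assert mr.alpha_coefficient(1.0, p) < 1e-20

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            mr.alpha_coefficient(0.0, self.p)


class TestBaseEquilibrium:
    def test_no_supply_factorizes(self):
        c_R, c_L, c_C = mr.solve_equilibrium_base(19.1, 0.0, 0.04519)
        assert (c_R, c_L, c_C) == (19.1, 0.0, 0.0)

    def test_first_contact_matches_bisection_oracle(self):
        c_D, S_L, alpha = -70.9, 90.0, 0.04519
        quad = lambda x: x**2 + (alpha - c_D) * x - alpha * (S_L + c_D)
        c_R_oracle = brentq(quad, 0.0, S_L + c_D, xtol=1e-14)
        c_R, c_L, c_C = mr.solve_equilibrium_base(c_D, S_L, alpha)
        assert c_R == pytest.approx(c_R_oracle, rel=1e-10)
        assert c_L == pytest.approx(70.912, abs=1e-3)
        assert c_C == pytest.approx(19.088, abs=1e-3)

    def test_weak_binding_limit_frees_all_receptors(self):
        c_R, c_L, c_C = mr.solve_equilibrium_base(-70.9, 90.0, 1e9)
        assert c_R == pytest.approx(19.1, rel=1e-6)
        assert c_C == pytest.approx(0.0, abs=1e-5)

    def test_infeasible_state_rejected(self):
        with pytest.raises(ValueError):
            mr.solve_equilibrium_base(-100.0, 90.0, 0.05)

    @given(
        c_tot=st.floats(0.0, 200.0),
        S_L=st.floats(0.0, 200.0),
        alpha=st.floats(1e-4, 10.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_closure_identity_and_bounds(self, c_tot, S_L, alpha):
        """The root satisfies the mass-action closure c_C alpha = c_R c_L and
        the bookkeeping identities, with all species nonnegative."""
        c_D = c_tot - S_L  # guarantees S_L + c_D = c_tot >= 0
        c_R, c_L, c_C = mr.solve_equilibrium_base(c_D, S_L, alpha)
        scale = max(1.0, c_tot, S_L, alpha)
        assert min(c_R, c_L, c_C) >= 0.0
        assert abs(c_C * alpha - c_R * c_L) <= 1e-9 * scale * scale
        assert c_L + c_C == pytest.approx(S_L, abs=1e-9 * scale)
        assert c_R + c_C == pytest.approx(c_tot, abs=1e-9 * scale)

    def test_monotone_in_supply_and_receptor_total(self):
        alpha = 0.04519
        grid = np.linspace(0.0, 150.0, 40)
        c_C_S = [mr.solve_equilibrium_base(19.1 - S, S, alpha)[2] for S in grid]
        assert np.all(np.diff(c_C_S) >= -1e-10)
        c_C_D = [mr.solve_equilibrium_base(c_D, 90.0, alpha)[2]
                 for c_D in np.linspace(-90.0, 60.0, 40)]
        assert np.all(np.diff(c_C_D) >= -1e-10)

    def test_complexes_never_exceed_available_ligands(self):
        c_R, c_L, c_C = mr.solve_equilibrium_base(500.0, 30.0, 1e-3)
        assert c_C < 30.0
        assert c_C == pytest.approx(30.0 * c_R / (1e-3 + c_R), rel=1e-6)


class TestSplitEquilibrium:
    def test_degenerate_split_matches_base(self):
        c_R_m, c_R_i, c_L, c_C_m, c_C_i = mr.solve_equilibrium_split(
            19.1, 0.0, 90.0, 0.04519)
        b_R, b_L, b_C = mr.solve_equilibrium_base(19.1 - 90.0, 90.0, 0.04519)
        assert c_R_m == pytest.approx(b_R, rel=1e-10)
        assert c_L == pytest.approx(b_L, rel=1e-10)
        assert c_C_m == pytest.approx(b_C, rel=1e-10)
        assert c_R_i == c_C_i == 0.0

    def test_no_supply_keeps_pools_free(self):
        out = mr.solve_equilibrium_split(14.707, 4.393, 0.0, 0.04519)
        assert out == (14.707, 4.393, 0.0, 0.0, 0.0)

    def test_first_contact_matches_scalar_bisection_oracle(self):
        c_m, c_i, S_L, alpha = 14.707, 4.393, 90.0, 0.04519
        eq = lambda cL: cL * (1.0 + (c_m + c_i) / (alpha + cL)) - S_L
        c_L_oracle = brentq(eq, 0.0, S_L, xtol=1e-14)
        c_R_m, c_R_i, c_L, c_C_m, c_C_i = mr.solve_equilibrium_split(c_m, c_i, S_L, alpha)
        assert c_L == pytest.approx(c_L_oracle, rel=1e-10)
        assert c_C_m + c_C_i == pytest.approx(19.088, abs=1e-3)
        assert c_R_m + c_R_i == pytest.approx(0.0122, abs=1e-4)
        # free receptors split in proportion to the pool totals
        assert c_R_m / c_R_i == pytest.approx(14.707 / 4.393, rel=1e-10)

    @given(
        c_m=st.floats(0.0, 50.0),
        c_i=st.floats(0.0, 50.0),
        S_L=st.floats(0.0, 150.0),
        alpha=st.floats(1e-4, 10.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_pool_consistency(self, c_m, c_i, S_L, alpha):
        c_R_m, c_R_i, c_L, c_C_m, c_C_i = mr.solve_equilibrium_split(c_m, c_i, S_L, alpha)
        scale = max(1.0, c_m + c_i, S_L, alpha)
        assert c_R_m + c_C_m == pytest.approx(c_m, abs=1e-10 * scale)
        assert c_R_i + c_C_i == pytest.approx(c_i, abs=1e-10 * scale)
        assert c_L + c_C_m + c_C_i == pytest.approx(S_L, abs=1e-9 * scale)
        assert min(c_R_m, c_R_i, c_L, c_C_m, c_C_i) >= 0.0


class TestMassActionRate:
    def test_pure_forward_is_positive(self):
        assert mr.mass_action_rate(0.3, 0.4, 0.0, 1.0, 1.0) > 0.0

    def test_half_occupancies(self):
        assert mr.mass_action_rate(0.5, 0.5, 0.5, 2.0, 1.0) == pytest.approx(1.0)

    def test_equilibrium_occupancies_give_zero_rate(self):
        # pick theta_C so that the occupancy ratios satisfy kf/kb
        kf, kb = 3.0, 1.0
        th_R, th_L = 0.2, 0.3
        x = kf / kb * (th_L / (1 - th_L)) * (th_R / (1 - th_R))
        th_C = x / (1.0 + x)
        assert mr.mass_action_rate(th_R, th_L, th_C, kf, kb) == pytest.approx(0.0, abs=1e-14)

    def test_saturation_violation_rejected(self):
        with pytest.raises(ValueError):
            mr.mass_action_rate(1.0, 0.5, 0.5, 1.0, 1.0)
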