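"""Closed-form kinetic laws against brute-force oracles and limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from kexlitmus import (
    Mechanism,
    MechanismParams,
    TitrationDesign,
    bound_fraction,
    kd_for_mechanism,
    kex_conf_selection,
    kex_curve,
    kex_induced_fit,
    kex_two_state,
    ligand_eq,
    relaxation_oracle,
)

conc = st.floats(min_value=1e-9, max_value=1e-1)
rate = st.floats(min_value=1.0, max_value=1e6)


class TestLigandEq:
    def test_no_protein_returns_total_ligand(self):
        assert ligand_eq(5e-4, 0.0, 1e-4) == 5e-4

    def test_no_ligand_returns_zero(self):
        assert ligand_eq(0.0, 1e-3, 3.7e-4) == 0.0

    def test_equimolar_matches_bisection_oracle(self):
        L0, P0, Kd = 1e-3, 1e-3, 3.7e-4
        # independent root of the mass balance L + P0*L/(Kd+L) - L0 = 0
        oracle = brentq(lambda L: L + P0 * L / (Kd + L) - L0, 0.0, L0, xtol=1e-18)
        L = ligand_eq(L0, P0, Kd)
        assert L == pytest.approx(oracle, rel=1e-10)
        assert abs(L + P0 * L / (Kd + L) - L0) < 1e-12

    def test_stoichiometric_limit_kd_zero(self):
        assert ligand_eq(1e-3, 4e-4, 0.0) == pytest.approx(6e-4)
        assert ligand_eq(4e-4, 1e-3, 0.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ligand_eq(-1e-3, 1e-3, 1e-4)

    @settings(max_examples=200, deadline=None)
    @given(L0=conc, P0=conc, Kd=conc)
    def test_mass_balance_residual_and_bounds(self, L0, P0, Kd):
        L = ligand_eq(L0, P0, Kd)
        assert 0.0 <= L <= L0
        resid = L + P0 * L / (Kd + L) - L0
        assert abs(resid) <= 1e-10 * max(L0, P0, Kd)

    def test_excess_ligand_asymptote(self):
        # L0 >> P0 + Kd: [L]_eq -> L0 - P0 + O(Kd)
        L = ligand_eq(1.0, 1e-3, 1e-6)
        assert L == pytest.approx(1.0 - 1e-3, abs=1e-5)


class TestKexLaws:
    def test_two_state_intercept_and_arithmetic(self):
        p = MechanismParams.two_state(6.5e6, 2420.0)
        assert kex_two_state(p, 0.0) == 2420.0
        assert kex_two_state(p, 1e-4) == pytest.approx(3070.0)
        p0 = MechanismParams.two_state(0.0, 2420.0)
        assert kex_two_state(p0, 5e-3) == 2420.0

    def test_two_state_rejects_cs_params(self, cs_params):
        with pytest.raises(ValueError):
            kex_two_state(cs_params, 1e-4)

    def test_cs_zero_ligand_limit(self):
        # at [L]_eq = 0 the slow rate is min(k12+k21, k_minus)
        p = MechanismParams.conf_selection(1280.0, 18720.0, 1e8, 2420.0)
        assert kex_conf_selection(p, 0.0) == pytest.approx(2420.0, rel=1e-12)
        p2 = MechanismParams.conf_selection(100.0, 200.0, 1e8, 5000.0)
        assert kex_conf_selection(p2, 0.0) == pytest.approx(300.0, rel=1e-12)

    def test_cs_saturation_plateau_is_k12(self, cs_params):
        Kd = kd_for_mechanism(cs_params)
        assert kex_conf_selection(cs_params, 1e6 * Kd) == pytest.approx(
            cs_params.k12, rel=1e-3
        )

    def test_if_degenerate_zero_ligand(self):
        p = MechanismParams.induced_fit(0.0, 300.0, 1e8, 5000.0)
        assert kex_induced_fit(p, 0.0) == pytest.approx(300.0, rel=1e-12)

    def test_if_saturation_plateau_is_conf_exchange(self):
        p = MechanismParams.induced_fit(1280.0, 18720.0, 1e8, 2420.0)
        Kd = kd_for_mechanism(p)
        assert kex_induced_fit(p, 1e6 * Kd) == pytest.approx(20000.0, rel=1e-3)

    @settings(max_examples=150, deadline=None)
    @given(k12=rate, k21=rate, kp=rate, km=rate, l1=conc, l2=conc)
    def test_if_monotone_increasing(self, k12, k21, kp, km, l1, l2):
        p = MechanismParams.induced_fit(k12, k21, kp, km)
        lo, hi = sorted((l1, l2))
        assert kex_induced_fit(p, hi) >= kex_induced_fit(p, lo) * (1 - 1e-9)


class TestKd:
    def test_two_state_identity(self):
        p = MechanismParams.two_state(2420.0 / 3.7e-4, 2420.0)
        assert kd_for_mechanism(p) == pytest.approx(3.7e-4)

    def test_cs_fully_competent(self):
        p = MechanismParams.conf_selection(500.0, 0.0, 1e8, 2420.0)
        assert kd_for_mechanism(p) == pytest.approx(2420.0 / 1e8)

    def test_cs_closed_form_vs_jump_equilibrium(self, cs_params):
        Kd = kd_for_mechanism(cs_params)
        expect = cs_params.k_minus * (cs_params.k12 + cs_params.k21) / (
            cs_params.k_plus * cs_params.k12
        )
        assert Kd == pytest.approx(expect, rel=1e-12)
        # at [L]_eq = K_d the jump process is half bound
        assert bound_fraction(cs_params, Kd) == pytest.approx(0.5, rel=1e-12)

    def test_if_half_occupancy_at_kd(self):
        p = MechanismParams.induced_fit(700.0, 3000.0, 5e7, 1800.0)
        assert bound_fraction(p, kd_for_mechanism(p)) == pytest.approx(0.5, rel=1e-12)

    def test_cs_unbindable_without_excitation(self):
        p = MechanismParams.conf_selection(0.0, 200.0, 1e8, 2420.0)
        with pytest.raises(ZeroDivisionError):
            kd_for_mechanism(p)

    @settings(max_examples=100, deadline=None)
    @given(k12=rate, k21=rate, kp=rate, km=rate)
    def test_kd_ordering(self, k12, k21, kp, km):
        # selecting a rare state is penalized; inducing the fit is not
        cs = MechanismParams.conf_selection(k12, k21, kp, km)
        iff = MechanismParams.induced_fit(k12, k21, kp, km)
        assert kd_for_mechanism(cs) >= km / kp * (1 - 1e-12)
        assert kd_for_mechanism(iff) <= km / kp * (1 + 1e-12)


class TestOracle:
    def test_generator_columns_sum_to_zero(self, cs_params):
        from kexlitmus.mechanisms import _generator

        G = _generator(cs_params, 1e-4)
        assert np.allclose(G.sum(axis=0), 0.0, atol=1e-9)

    def test_exactly_one_zero_eigenvalue(self, cs_params):
        from kexlitmus.mechanisms import _generator

        G = _generator(cs_params, 1e-4)
        lams = np.sort(np.abs(np.linalg.eigvals(G)))
        assert lams[0] < 1e-10 * np.abs(G).max()
        assert lams[1] > 1e-10 * np.abs(G).max()

    def test_two_state_eigenvalue_exact(self, rng):
        for _ in range(50):
            kon, koff = 10 ** rng.uniform(0, 6, 2)
            L = 10 ** rng.uniform(-6, -2)
            p = MechanismParams.two_state(kon, koff)
            assert relaxation_oracle(p, L)[0] == pytest.approx(
                kex_two_state(p, L), rel=1e-12
            )

    def test_three_state_smallest_eigenvalue_matches_closed_form(self, rng):
        for _ in range(300):
            k12, k21, kp, km = 10 ** rng.uniform(0, 6, 4)
            L = 10 ** rng.uniform(-6, -2)
            cs = MechanismParams.conf_selection(k12, k21, kp, km)
            iff = MechanismParams.induced_fit(k12, k21, kp, km)
            assert relaxation_oracle(cs, L)[0] == pytest.approx(
                kex_conf_selection(cs, L), rel=1e-9
            )
            assert relaxation_oracle(iff, L)[0] == pytest.approx(
                kex_induced_fit(iff, L), rel=1e-9
            )


class TestKexCurve:
    def test_two_state_zero_ligand(self, ts_params):
        design = TitrationDesign(P0=1e-3, L0_series=(0.0,))
        assert kex_curve(ts_params, design)[0][1] == ts_params.k_off

    def test_cs_direction_follows_k12_vs_kminus(self, titration):
        slow = MechanismParams.conf_selection(1280.0, 18720.0, 1e8, 2420.0)
        fast = MechanismParams.conf_selection(5000.0, 15000.0, 1e8, 1000.0)
        k_slow = [k for _, k in kex_curve(slow, titration)]
        k_fast = [k for _, k in kex_curve(fast, titration)]
        assert all(b < a for a, b in zip(k_slow, k_slow[1:]))  # k12 < k-: decreasing
        assert all(b > a for a, b in zip(k_fast, k_fast[1:]))  # k12 > k-: increasing

    def test_curve_matches_pointwise_oracle(self, cs_params, titration):
        Kd = kd_for_mechanism(cs_params)
        for L0, kex in kex_curve(cs_params, titration):
            L_eq = ligand_eq(L0, titration.P0, Kd)
            assert kex == pytest.approx(relaxation_oracle(cs_params, L_eq)[0], rel=1e-9)


class TestParamValidation:
    def test_ts_missing_rates_rejected(self):
        with pytest.raises(ValueError):
            MechanismParams(Mechanism.TS, k_on=1e6)

    def test_foreign_fields_rejected(self):
        with pytest.raises(ValueError):
            MechanismParams(Mechanism.TS, k_on=1e6, k_off=100.0, k12=5.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            MechanismParams.conf_selection(-1.0, 100.0, 1e6, 10.0)

    def test_titration_requires_increasing_series(self):
        with pytest.raises(ValueError):
            TitrationDesign(P0=1e-3, L0_series=(1e-4, 1e-4))
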