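"""Intensity conversion, Luz-Meiboom model and joint multi-field fitting."""

import math

import numpy as np
import pytest

from kexlitmus import (
    DispersionCurve,
    IntensityRecord,
    estimate_uncertainties,
    fit_dispersion_joint,
    luz_meiboom_r2eff,
    r2eff_from_intensities,
)
from kexlitmus.dispersion import b0_scale

FIELDS = (60.795, 96.313)


def make_curves(nu_grid, kex=4000.0, psi=0.25, r20=(10.0, 12.0), sigma=0.4,
                noise_rng=None, L0=5e-4):
    curves = []
    for f, r in zip(FIELDS, r20):
        r2 = np.array([luz_meiboom_r2eff(r, psi, f, kex, v) for v in nu_grid])
        if noise_rng is not None:
            r2 = r2 + sigma * noise_rng.standard_normal(len(nu_grid))
        curves.append(
            DispersionCurve("R49", f, L0, tuple(nu_grid), tuple(r2),
                            tuple([sigma] * len(nu_grid)))
        )
    return curves


class TestR2effFromIntensities:
    def test_no_decay(self):
        ref = IntensityRecord("r", None, 100.0, 0.06)
        rec = IntensityRecord("r", 667.0, 100.0, 0.06)
        assert r2eff_from_intensities(rec, ref) == 0.0

    def test_half_intensity_sixty_ms(self):
        ref = IntensityRecord("r", None, 1.0, 0.06)
        rec = IntensityRecord("r", 667.0, 0.5, 0.06)
        assert r2eff_from_intensities(rec, ref) == pytest.approx(math.log(2) / 0.06)

    def test_unit_case(self):
        ref = IntensityRecord("r", None, 1.0, 1.0)
        rec = IntensityRecord("r", 100.0, math.exp(-1.0), 1.0)
        assert r2eff_from_intensities(rec, ref) == pytest.approx(1.0)

    def test_mismatched_residues_rejected(self):
        ref = IntensityRecord("a", None, 1.0, 0.06)
        rec = IntensityRecord("b", 667.0, 0.5, 0.06)
        with pytest.raises(ValueError):
            r2eff_from_intensities(rec, ref)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            IntensityRecord("r", 667.0, 0.0, 0.06)


class TestLuzMeiboom:
    def test_fast_pulsing_refocuses_to_baseline(self):
        assert luz_meiboom_r2eff(10.0, 0.3, 96.313, 4000.0, 1e9) == pytest.approx(
            10.0, abs=1e-3
        )

    def test_slow_pulsing_plateau(self):
        kex = 4000.0
        plateau = 10.0 + 0.3 * b0_scale(96.313) ** 2 / kex
        assert luz_meiboom_r2eff(10.0, 0.3, 96.313, kex, kex / 1e4) == pytest.approx(
            plateau, rel=1e-3
        )

    def test_non_increasing_in_nu(self, rng, snapped_nu_grid):
        for _ in range(30):
            kex = 10 ** rng.uniform(2.5, 4.7)
            psi = 10 ** rng.uniform(-3, 0)
            r2 = [luz_meiboom_r2eff(8.0, psi, 96.313, kex, v) for v in snapped_nu_grid]
            assert all(b <= a + 1e-12 for a, b in zip(r2, r2[1:]))

    def test_exchange_term_scales_as_field_squared(self):
        nu, kex, psi = 133.0, 4000.0, 0.3
        ex = [luz_meiboom_r2eff(0.0, psi, f, kex, nu) for f in FIELDS]
        assert ex[1] / ex[0] == pytest.approx((96.313 / 60.795) ** 2, rel=1e-12)


class TestJointFit:
    def test_noiseless_round_trip(self, snapped_nu_grid):
        curves = make_curves(snapped_nu_grid)
        res = fit_dispersion_joint(curves)
        assert res.converged and not res.no_dispersion
        assert res.kex == pytest.approx(4000.0, rel=1e-6)
        assert res.psi_ex == pytest.approx(0.25, rel=1e-6)
        assert res.R20_per_field[60.795] == pytest.approx(10.0, rel=1e-6)
        assert res.R20_per_field[96.313] == pytest.approx(12.0, rel=1e-6)

    def test_single_field_three_parameters(self, snapped_nu_grid):
        curves = make_curves(snapped_nu_grid)[:1]
        res = fit_dispersion_joint(curves)
        assert res.converged
        assert res.kex == pytest.approx(4000.0, rel=1e-5)

    def test_point_order_and_sigma_scale_invariance(self, rng, snapped_nu_grid):
        curves = make_curves(snapped_nu_grid, noise_rng=rng)
        res = fit_dispersion_joint(curves)
        # uniform sigma rescale: same point estimates, errors scale
        scaled = [
            DispersionCurve(c.residue_id, c.field_MHz, c.L0, c.nu_cpmg, c.R2eff,
                            tuple(3.0 * s for s in c.sigma))
            for c in curves
        ]
        res3 = fit_dispersion_joint(scaled)
        assert res3.kex == pytest.approx(res.kex, rel=1e-6)
        assert res3.kex_sigma == pytest.approx(res.kex_sigma, rel=1e-4)
        # field order must not matter
        res_r = fit_dispersion_joint(curves[::-1])
        assert res_r.kex == pytest.approx(res.kex, rel=1e-8)

    def test_flat_profile_flagged_no_dispersion(self, rng, snapped_nu_grid):
        n = len(snapped_nu_grid)
        curves = [
            DispersionCurve("r", f, 1e-4, snapped_nu_grid,
                            tuple(10.0 + 0.3 * rng.standard_normal(n)),
                            tuple([0.3] * n))
            for f in FIELDS
        ]
        res = fit_dispersion_joint(curves)
        assert res.no_dispersion

    def test_too_few_points_rejected(self):
        nu = (100.0, 200.0, 400.0, 800.0)
        c = DispersionCurve("r", 60.795, 1e-4, nu, (12, 11, 10.5, 10.2), (1, 1, 1, 1))
        fit_dispersion_joint([c])  # 4 points, 3 params: fine
        with pytest.raises(ValueError):
            fit_dispersion_joint([])

    def test_monte_carlo_calibration(self, rng, snapped_nu_grid):
        """At sigma = 0.4 s^-1 the kex estimator is unbiased within its
        error and the 1-sigma interval covers truth at roughly 68%."""
        kex_true = 4000.0
        hits, ests, sigs = 0, [], []
        n_rep = 200
        for _ in range(n_rep):
            res = fit_dispersion_joint(make_curves(snapped_nu_grid, noise_rng=rng))
            if not res.converged:
                continue
            ests.append(res.kex)
            sigs.append(res.kex_sigma)
            if abs(res.kex - kex_true) <= res.kex_sigma:
                hits += 1
        assert len(ests) > 0.95 * n_rep
        med_sigma = float(np.median(sigs))
        assert abs(np.median(ests) - kex_true) < med_sigma
        assert 0.5 < hits / len(ests) < 0.85


class TestUncertainties:
    def make_panel(self, rng, sigma_noise=0.3, n_nu=14, n_flat=5, n_exch=6):
        data = {}
        for i in range(n_flat):
            data[f"flat{i}"] = 10.0 + sigma_noise * rng.standard_normal(n_nu)
        for i in range(n_exch):
            disp = np.linspace(8.0, 0.0, n_nu)  # strong dispersion
            data[f"ex{i}"] = 12.0 + disp + sigma_noise * rng.standard_normal(n_nu)
        return data

    def test_auto_selection_prefers_flat_residues(self, rng):
        data = self.make_panel(rng)
        model = estimate_uncertainties(data, repeats={})
        assert set(model.reference_residues) == {f"flat{i}" for i in range(5)}

    def test_global_sigma_recovers_injected_noise(self, rng):
        data = self.make_panel(rng)
        model = estimate_uncertainties(data, repeats={})
        assert model.sigma_global == pytest.approx(0.3, rel=0.35)

    def test_identical_repeats_fall_back_to_global(self, rng):
        data = self.make_panel(rng)
        model = estimate_uncertainties(
            data, repeats={"ex0": np.array([15.0, 15.0, 15.0])}
        )
        assert model.sigma_residue["ex0"] == 0.0
        assert model.sigma_for("ex0") == model.sigma_global

    def test_large_repeat_scatter_dominates(self, rng):
        data = self.make_panel(rng)
        model = estimate_uncertainties(
            data, repeats={"ex1": np.array([14.0, 16.0, 18.0])}
        )
        assert model.sigma_for("ex1") == model.sigma_residue["ex1"]
        assert model.sigma_for("ex1") > model.sigma_global

    def test_missing_repeats_warn(self, rng):
        data = self.make_panel(rng)
        with pytest.warns(UserWarning):
            estimate_uncertainties(data, repeats=None)
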