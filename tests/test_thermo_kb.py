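"""Activity models, Gibbs-Duhem consistency, KB inversion and the
activity-model fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sasamc import constants as c
from sasamc.thermo_kb import (ActivityModel, SolutionComposition,
                              activity_derivative_matrix, fit_activity_model,
                              gibbs_duhem_residual, kb_forward, kb_invert,
                              ks_from_gamma23, ks_model, ln_a1, ln_gamma2,
                              ln_gamma3, osmolality,
                              _molality_derivative_matrix, VBAR_DEFAULT)

TABLE3_SALTING_OUT = ActivityModel(A2=-7.2399, B2=24.9741, C1=0.8061,
                                   C2=-8.0176, A3=-0.3506, B3=0.2087, nu3=3)
TABLE3_SALTING_IN = ActivityModel(A2=-7.2399, B2=24.9741, C1=-1.1145,
                                  C2=6.1971, A3=-0.6216, B3=0.4754, nu3=3)
TABLE2_NA2SO4 = ActivityModel(C1=3.84, C2=-28.59, nu3=3)


class TestActivityModel:
    def test_infinite_dilution_reference(self):
        comp = SolutionComposition(0.0, 0.0)
        assert ln_gamma2(comp, TABLE3_SALTING_OUT) == 0.0
        assert ln_a1(comp, TABLE3_SALTING_OUT) == 0.0
        assert ln_gamma3(0.0, TABLE3_SALTING_OUT) == 0.0

    def test_binary_caffeine_slice_value(self):
        """A2·m2 + B2·m2² at m2 = 0.05 from the printed caffeine binary
        coefficients."""
        comp = SolutionComposition(0.05, 0.0)
        assert ln_gamma2(comp, TABLE3_SALTING_OUT) == pytest.approx(
            -0.2996, abs=2e-4)

    def test_salting_out_constant_is_salt_slope(self):
        """∂ln γ₂/∂m₃ equals C1 + C2·m2 (enforced analytic contract) and
        reproduces the printed self-consistent value 2.41 at 0.05."""
        m2 = 0.05
        h = 1e-7
        num = (ln_gamma2(SolutionComposition(m2, h), TABLE2_NA2SO4)
               - ln_gamma2(SolutionComposition(m2, 0.0), TABLE2_NA2SO4)) / h
        assert num == pytest.approx(ks_model(m2, TABLE2_NA2SO4), rel=1e-6)
        assert ks_model(0.05, TABLE2_NA2SO4) == pytest.approx(2.41, abs=0.005)

    def test_ideal_water_activity(self):
        ideal = ActivityModel(nu3=3)
        comp = SolutionComposition(0.05, 0.1)
        assert ln_a1(comp, ideal) == pytest.approx(-c.M1_WATER * 0.35,
                                                   rel=1e-12)

    def test_ideal_salt_activity_is_zero(self):
        ideal = ActivityModel(nu3=2)
        for m3 in (0.0, 0.1, 0.5):
            assert ln_gamma3(m3, ideal) == 0.0

    def test_nonideality_factor_matches_finite_difference(self):
        """(1 + ∂ln γ₃±/∂ln m₃) used in the k_s relation against central
        differences of ln_gamma3."""
        model = TABLE3_SALTING_OUT
        for m3 in (0.05, 0.2, 0.45):
            h = 1e-7
            dlng = (ln_gamma3(m3 + h, model) - ln_gamma3(m3 - h, model)) \
                / (2 * h)
            analytic = model.A3 + 2 * model.B3 * m3
            assert dlng == pytest.approx(analytic, rel=1e-6)

    def test_osmolality_residual_structure(self):
        """ΔOsm of the model surface is exactly (C1 + C2·m2)·m2·m3."""
        model = TABLE3_SALTING_IN
        m2, m3 = 0.04, 0.3
        d = (osmolality(SolutionComposition(m2, m3), model)
             - osmolality(SolutionComposition(m2, 0.0), model)
             - osmolality(SolutionComposition(0.0, m3), model))
        assert d == pytest.approx((model.C1 + model.C2 * m2) * m2 * m3,
                                  rel=1e-10)


class TestGibbsDuhem:
    @pytest.mark.parametrize("model", [TABLE3_SALTING_OUT, TABLE3_SALTING_IN,
                                       ActivityModel(nu3=2)])
    def test_residual_below_tolerance_on_random_paths(self, model, rng):
        pts = rng.random((5, 2)) * [0.05, 0.5] + 1e-4
        resid = gibbs_duhem_residual(model, pts)
        assert resid < 1e-7

    def test_molality_derivative_rows_satisfy_gd_exactly(self):
        comp = SolutionComposition(0.03, 0.25)
        D = _molality_derivative_matrix(comp, TABLE3_SALTING_OUT)
        n = np.array([1.0 / c.M1_WATER, comp.m2, comp.m3])
        assert np.allclose(n @ D, 0.0, atol=1e-12)

    def test_maxwell_symmetry_of_cross_derivatives(self):
        comp = SolutionComposition(0.02, 0.3)
        D = _molality_derivative_matrix(comp, TABLE3_SALTING_OUT)
        assert D[1, 1] == pytest.approx(D[2, 0], rel=1e-12)


class TestActivityDerivativeMatrix:
    def test_ideal_solution_structure(self):
        ideal = ActivityModel(nu3=2)
        a = activity_derivative_matrix(SolutionComposition(0.02, 0.1), ideal)
        # solute rows: d ln a_j / d ln m_j = 1, cross terms vanish
        assert a[1, 0] == pytest.approx(1.0)
        assert a[2, 1] == pytest.approx(1.0)
        assert a[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert a[2, 0] == pytest.approx(0.0, abs=1e-12)

    def test_finite_difference_agreement(self, rng):
        model = TABLE3_SALTING_OUT
        for _ in range(5):
            m2 = 0.001 + 0.05 * rng.random()
            m3 = 0.001 + 0.5 * rng.random()
            a = activity_derivative_matrix(SolutionComposition(m2, m3), model)
            h = 1e-6

            def lna(j, mm2, mm3):
                compx = SolutionComposition(mm2, mm3)
                if j == 0:
                    return ln_a1(compx, model)
                if j == 1:
                    return np.log(mm2) + ln_gamma2(compx, model)
                return np.log(mm3) + ln_gamma3(mm3, model, m2=mm2)

            for j in range(3):
                num2 = (lna(j, m2 * (1 + h), m3)
                        - lna(j, m2 * (1 - h), m3)) / (2 * h)
                num3 = (lna(j, m2, m3 * (1 + h))
                        - lna(j, m2, m3 * (1 - h))) / (2 * h)
                assert a[j, 0] == pytest.approx(num2, rel=1e-5, abs=1e-9)
                assert a[j, 1] == pytest.approx(num3, rel=1e-5, abs=1e-9)


class TestKbInversion:
    def test_round_trip_reproduces_derivatives(self):
        model = TABLE3_SALTING_OUT
        for m2, m3 in [(0.01, 0.05), (0.03, 0.25), (0.05, 0.5)]:
            comp = SolutionComposition(m2, m3)
            vbar = (18.14, 145.9, 16.62)
            kb = kb_invert(comp, model, vbar=vbar)
            D0 = _molality_derivative_matrix(comp, model)
            D1, kTkappa, vbar_rec = kb_forward(kb, comp)
            assert np.allclose(D1, D0, rtol=1e-8)
            # volumetric inputs recovered exactly
            expected_kTk = 1.380649e-23 * comp.T * kb.kappa_T * 1e30
            assert kTkappa == pytest.approx(expected_kTk, rel=1e-8)
            assert np.allclose(vbar_rec,
                               np.array(vbar) * 1e24 / c.AVOGADRO, rtol=1e-8)

    def test_symmetry_and_finiteness_over_table3_grid(self):
        model = TABLE3_SALTING_IN
        vbar = (18.14, 145.9, 40.96)
        for m2 in np.linspace(0.0, 0.05, 4):
            for m3 in np.linspace(0.0, 0.5, 4):
                kb = kb_invert(SolutionComposition(m2, m3), model, vbar=vbar)
                assert np.allclose(kb.G, kb.G.T)
                assert np.all(np.isfinite(kb.G))
                # reciprocity of excess coordination numbers
                N = kb.N
                assert np.allclose(N / kb.rho[None, :],
                                   (N / kb.rho[None, :]).T)

    def test_infinite_dilution_solute_water_kb_integral(self):
        """Binary dilute limit: G12 → kT·κ_T − V̄₂ (the textbook
        relation between the solute-water KB integral, compressibility
        and the solute partial molar volume)."""
        model = ActivityModel(A2=0.0, B2=0.0, nu3=2)
        comp = SolutionComposition(1e-6, 0.0)
        kb = kb_invert(comp, model)
        kTkappa = 1.380649e-23 * comp.T * kb.kappa_T * 1e30
        vbar2 = VBAR_DEFAULT[1] * 1e24 / c.AVOGADRO
        assert kb.G[0, 1] == pytest.approx(kTkappa - vbar2, rel=1e-3)

    def test_smooth_g22_surface(self):
        model = TABLE3_SALTING_OUT
        vbar = (18.14, 145.9, 16.62)
        g22 = [kb_invert(SolutionComposition(m2, 0.2), model, vbar=vbar).G[1, 1]
               for m2 in np.linspace(0.001, 0.05, 8)]
        assert np.all(np.isfinite(g22))
        assert np.max(np.abs(np.diff(g22, 2))) < 0.2 * np.max(np.abs(g22))


class TestFitActivityModel:
    @staticmethod
    def grid(model, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for m2 in (0.0125, 0.025, 0.0375, 0.05):
            for m3 in (0.0, 0.1, 0.25, 0.5):
                lg = ln_gamma2(SolutionComposition(m2, m3), model)
                if noise:
                    lg += rng.normal(0.0, noise)
                rows.append(dict(m2=m2, m3=m3, ln_gamma2=lg,
                                 stderr=noise if noise else np.nan))
        return pd.DataFrame(rows)

    def test_noiseless_exact_recovery(self):
        model = TABLE3_SALTING_OUT
        fit = fit_activity_model(self.grid(model), nu3=3)
        assert fit.model.A2 == pytest.approx(model.A2, abs=1e-9)
        assert fit.model.B2 == pytest.approx(model.B2, abs=1e-8)
        assert fit.model.C1 == pytest.approx(model.C1, abs=1e-9)
        assert fit.model.C2 == pytest.approx(model.C2, abs=1e-8)

    def test_noisy_recovery_within_confidence(self):
        """Monte-Carlo recovery: fitted coefficients match the
        generating truth within 2 fitted σ in ~95% of replicates."""
        model = TABLE3_SALTING_OUT
        hits = {"A2": 0, "C1": 0}
        n_rep = 150
        for rep in range(n_rep):
            fit = fit_activity_model(self.grid(model, noise=0.01, seed=rep),
                                     nu3=3)
            if abs(fit.model.A2 - model.A2) < 2.5 * fit.stderr["A2"]:
                hits["A2"] += 1
            if abs(fit.model.C1 - model.C1) < 2.5 * fit.stderr["C1"]:
                hits["C1"] += 1
        assert hits["A2"] > 0.85 * n_rep
        assert hits["C1"] > 0.85 * n_rep

    def test_insufficient_points_rejected(self):
        df = pd.DataFrame({"m2": [0.01], "m3": [0.0], "ln_gamma2": [0.0]})
        with pytest.raises(ValueError):
            fit_activity_model(df)


class TestKsFromGamma23:
    def test_zero_gamma_ideal_salt(self):
        assert ks_from_gamma23(0.0, 0.1, ActivityModel(nu3=2)) == 0.0
        assert ks_from_gamma23(0.0, 0.0, ActivityModel(nu3=2)) == 0.0

    def test_ideal_salt_reduces_to_proportionality(self):
        ideal = ActivityModel(nu3=2)
        assert ks_from_gamma23(-0.4, 0.2, ideal) == pytest.approx(2.0)

    def test_depletion_gives_salting_out_sign(self):
        model = TABLE3_SALTING_OUT
        assert ks_from_gamma23(-0.3, 0.2, model) > 0
        assert ks_from_gamma23(+0.3, 0.2, model) < 0

    def test_round_trip_through_kb_inversion(self):
        """Γ₂₃ from the inverted KB integrals, fed through the k_s
        relation, returns the generating C1 + C2·m2 in the dilute
        regime."""
        model = TABLE3_SALTING_OUT
        vbar = (18.14, 145.9, 16.62)
        m2, m3 = 0.005, 0.02
        comp = SolutionComposition(m2, m3)
        kb = kb_invert(comp, model, vbar=vbar)
        # ion-count Γ23 = ν3·ρ_salt·(G23 − G21)
        rho3_ions = model.nu3 * kb.rho[2]
        gamma23 = rho3_ions * (kb.G[1, 2] - kb.G[0, 1])
        ks = ks_from_gamma23(gamma23, m3, model)
        assert ks == pytest.approx(ks_model(m2, model), rel=0.1)
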