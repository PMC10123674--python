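import numpy as np
import pytest

from dscthermo import (
    R_KCAL,
    StatTwoStateParams,
    ZimmBraggParams,
    cold_denaturation_temperature,
    extent_unfolded,
    nucleation_free_energy,
    stat_two_state_lnZ,
    thermo_from_lnZ,
    zimm_bragg_lnZ,
)


class TestStatTwoState:
    def test_partition_function_is_two_at_midpoint(self, lysozyme_stat_params):
        lnz = stat_two_state_lnZ(lysozyme_stat_params, np.array([335.0]))
        assert lnz[0] == pytest.approx(np.log(2.0), rel=1e-14)

    def test_midpoint_free_energy(self, lysozyme_stat_params):
        # F(T_m) = -R T_m ln 2 = -0.46 kcal/mol at 335 K
        lnz = stat_two_state_lnZ(lysozyme_stat_params, np.array([335.0]))
        F = -R_KCAL * 335.0 * lnz[0]
        assert F == pytest.approx(-0.46, abs=0.005)

    def test_single_state_limit_deep_native(self):
        p = StatTwoStateParams(dE0=110.0, t_m=335.0, cv=0.0)
        t = np.linspace(260.0, 280.0, 10)
        lnz = stat_two_state_lnZ(p, t)
        assert np.all(lnz < 1e-8)

    def test_theta_crosses_half_at_both_midpoints(self, lysozyme_stat_params):
        t = np.arange(210.0, 380.0, 0.02)
        theta = extent_unfolded("stat_two_state", lysozyme_stat_params, t)
        crossings = t[:-1][np.diff(np.sign(theta - 0.5)) != 0]
        assert len(crossings) == 2
        t_cold = cold_denaturation_temperature(lysozyme_stat_params)
        assert crossings[0] == pytest.approx(t_cold, abs=0.05)
        assert crossings[1] == pytest.approx(335.0, abs=0.05)

    @pytest.mark.parametrize(
        "dE0, cv, tm, dT",
        [
            (110.0, 1.05, 335.0, 104.8),  # lysozyme
            (60.0, 1.25, 328.0, 48.0),  # beta-lactoglobulin heat+cold
        ],
    )
    def test_cold_denaturation_temperature(self, dE0, cv, tm, dT):
        p = StatTwoStateParams(dE0=dE0, t_m=tm, cv=cv)
        t_cold = cold_denaturation_temperature(p)
        assert tm - t_cold == pytest.approx(dT, abs=0.05)

    def test_no_cold_denaturation_without_cv(self):
        p = StatTwoStateParams(dE0=110.0, t_m=335.0, cv=0.0)
        assert cold_denaturation_temperature(p) is None

    def test_degenerate_zero_energy_gives_tcold_at_tm(self):
        p = StatTwoStateParams(dE0=0.0, t_m=335.0, cv=1.0)
        assert cold_denaturation_temperature(p) == pytest.approx(335.0)


class TestZimmBragg:
    def test_reduces_to_stat_two_state_at_sigma_one(self):
        zb = ZimmBraggParams(h0=110.0, cv_res=1.05, sigma=1.0, n_res=1, t_m=335.0)
        st = StatTwoStateParams(dE0=110.0, t_m=335.0, cv=1.05)
        t = np.arange(200.0, 400.0, 0.5)
        np.testing.assert_allclose(
            zimm_bragg_lnZ(zb, t), stat_two_state_lnZ(st, t), atol=1e-12
        )

    def test_theta_half_at_midpoint(self, lysozyme_zb_params):
        theta = extent_unfolded("zimm_bragg", lysozyme_zb_params, np.array([335.0]))
        assert theta[0] == pytest.approx(0.5, rel=1e-12)

    def test_smaller_sigma_sharpens_transition(self, lysozyme_zb_params):
        # full width at half maximum of the model C_p peak shrinks with sigma
        t = np.arange(300.0, 370.0, 0.02)

        def fwhm(sigma):
            p = ZimmBraggParams(
                h0=0.91, cv_res=0.007, sigma=sigma, n_res=129, t_m=335.0
            )
            cp = thermo_from_lnZ(zimm_bragg_lnZ(p, t), t).Cv_curve
            half = cp.max() / 2
            above = t[cp > half]
            return above[-1] - above[0]

        assert fwhm(5e-7) < fwhm(1e-2)

    def test_theta_matches_finite_difference_of_lnZ_in_s(self, lysozyme_zb_params):
        # theta_U = (s/N) dlnZ/ds: compare the analytic eigenvalue
        # derivative with a finite difference in ln s at fixed temperature
        p = lysozyme_zb_params
        t = np.array([320.0, 335.0, 350.0])
        h = p.h0 + p.cv_res * (t - p.t_m)
        s = np.exp(-h * (1 / (R_KCAL * t) - 1 / (R_KCAL * p.t_m)))
        eps = 1e-7

        def lnz_of_s(s_val):
            lam = 0.5 * (1 + s_val) + np.sqrt(
                (0.5 * (1 - s_val)) ** 2 + p.sigma * s_val
            )
            return p.n_res * np.log(lam)

        numeric = (lnz_of_s(s * (1 + eps)) - lnz_of_s(s * (1 - eps))) / (2 * eps)
        numeric /= p.n_res  # (s/N) dlnZ/ds = (1/N) dlnZ/dln s
        analytic = extent_unfolded("zimm_bragg", p, t)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6)

    def test_sigma_bounds_enforced(self):
        with pytest.raises(ValueError):
            ZimmBraggParams(h0=0.9, cv_res=0.007, sigma=0.0, n_res=129, t_m=335.0)
        with pytest.raises(ValueError):
            ZimmBraggParams(h0=0.9, cv_res=0.007, sigma=1.5, n_res=129, t_m=335.0)


class TestThermoFromLnZ:
    def test_single_state_gives_zero_thermodynamics(self):
        t = np.linspace(300.0, 310.0, 21)
        thermo = thermo_from_lnZ(np.zeros_like(t), t)
        for curve in (thermo.E, thermo.S, thermo.F, thermo.Cv_curve):
            np.testing.assert_allclose(curve, 0.0, atol=1e-12)

    def test_free_energy_never_positive(self, lysozyme_stat_params, lysozyme_zb_params):
        t = np.arange(220.0, 400.0, 0.1)
        for lnz in (
            stat_two_state_lnZ(lysozyme_stat_params, t),
            zimm_bragg_lnZ(lysozyme_zb_params, t),
        ):
            thermo = thermo_from_lnZ(lnz, t)
            assert np.all(thermo.F <= 1e-12)

    def test_entropy_construction_identity(self, lysozyme_stat_params):
        t = np.arange(280.0, 390.0, 0.1)
        thermo = thermo_from_lnZ(stat_two_state_lnZ(lysozyme_stat_params, t), t)
        np.testing.assert_allclose(
            thermo.S, (thermo.E - thermo.F) / t, rtol=0, atol=1e-9
        )

    def test_cv_matches_fluctuation_identity_for_fixed_levels(self):
        # with temperature-independent level energies, Cv must equal the
        # Boltzmann fluctuation form (<E^2>-<E>^2)/(R T^2)
        p = StatTwoStateParams(dE0=110.0, t_m=335.0, cv=0.0)
        t = np.arange(320.0, 350.0, 0.002)
        thermo = thermo_from_lnZ(stat_two_state_lnZ(p, t), t)
        # two levels at 0 and dE, with the midpoint-referenced weight
        x = -110.0 * (1 / (R_KCAL * t) - 1 / (R_KCAL * 335.0))
        w = np.exp(x) / (1 + np.exp(x))
        mean_e = 110.0 * w
        var_e = 110.0**2 * w - mean_e**2
        fluct = var_e / (R_KCAL * t**2)
        interior = slice(5, -5)
        np.testing.assert_allclose(
            thermo.Cv_curve[interior], fluct[interior], rtol=1e-4
        )

    def test_model_cp_integrates_back_to_energy_rise(self, lysozyme_stat_params):
        t = np.arange(300.0, 370.0, 0.02)
        thermo = thermo_from_lnZ(stat_two_state_lnZ(lysozyme_stat_params, t), t)
        area = np.trapezoid(thermo.Cv_curve, t)
        assert area == pytest.approx(thermo.E[-1] - thermo.E[0], rel=1e-6)

    def test_energy_rise_matches_reported_total(self, lysozyme_stat_params):
        # total inner-energy rise across the lysozyme transition window
        t = np.arange(318.0, 346.0, 0.02)
        thermo = thermo_from_lnZ(stat_two_state_lnZ(lysozyme_stat_params, t), t)
        assert thermo.E[-1] - thermo.E[0] == pytest.approx(132.3, rel=0.05)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            thermo_from_lnZ(np.zeros(4), np.linspace(300, 301, 4))

    def test_derivative_step_refinement_converges(self, lysozyme_stat_params):
        totals = {}
        for step in (0.5, 0.05, 0.005):
            t = np.arange(300.0, 370.0 + step / 2, step)
            thermo = thermo_from_lnZ(stat_two_state_lnZ(lysozyme_stat_params, t), t)
            totals[step] = thermo.E[-1] - thermo.E[0]
        err_coarse = abs(totals[0.5] - totals[0.005])
        err_fine = abs(totals[0.05] - totals[0.005])
        assert err_fine < err_coarse / 5.0


class TestExtentUnfolded:
    def test_both_models_half_unfolded_at_tm(
        self, lysozyme_stat_params, lysozyme_zb_params
    ):
        t = np.array([335.0])
        assert extent_unfolded("stat_two_state", lysozyme_stat_params, t)[
            0
        ] == pytest.approx(0.5, rel=1e-12)
        assert extent_unfolded("zimm_bragg", lysozyme_zb_params, t)[
            0
        ] == pytest.approx(0.5, rel=1e-12)

    def test_deep_native_limit_zero(self, lysozyme_stat_params, lysozyme_zb_params):
        t = np.array([300.0])
        assert extent_unfolded("stat_two_state", lysozyme_stat_params, t)[0] < 1e-3
        assert extent_unfolded("zimm_bragg", lysozyme_zb_params, t)[0] < 1e-3

    def test_bounded_and_locally_monotone(self, lysozyme_stat_params):
        t = np.arange(240.0, 390.0, 0.1)
        theta = extent_unfolded("stat_two_state", lysozyme_stat_params, t)
        assert np.all((theta >= 0) & (theta <= 1))
        # monotone on each side of the native minimum
        i_min = int(np.argmin(theta))
        assert np.all(np.diff(theta[: i_min + 1]) <= 1e-15)
        assert np.all(np.diff(theta[i_min:]) >= -1e-15)

    def test_midpoint_separation_equals_energy_ratio(self, lysozyme_stat_params):
        t = np.arange(210.0, 380.0, 0.05)
        theta = extent_unfolded("stat_two_state", lysozyme_stat_params, t)
        crossings = t[:-1][np.diff(np.sign(theta - 0.5)) != 0]
        dT = crossings[-1] - crossings[0]
        assert dT == pytest.approx(
            lysozyme_stat_params.dE0 / lysozyme_stat_params.cv, abs=0.1
        )


class TestNucleationFreeEnergy:
    @pytest.mark.parametrize(
        "sigma, temperature, expected",
        [
            (5e-7, 335.0, 9.6),  # lysozyme
            (7e-5, 326.0, 6.2),  # beta-lactoglobulin
        ],
    )
    def test_published_nucleation_energies(self, sigma, temperature, expected):
        assert nucleation_free_energy(sigma, temperature) == pytest.approx(
            expected, rel=0.02
        )

    def test_no_cooperativity_means_no_barrier(self):
        assert nucleation_free_energy(1.0, 335.0) == 0.0

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            nucleation_free_energy(0.0, 335.0)
        with pytest.raises(ValueError):
            nucleation_free_energy(2.0, 335.0)
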