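"""ITC isotherm/fit, FP direct and competition models, pull-down Ki, C_eff."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from fn3kit import binding
from fn3kit.simulate import gen_fp_competition, gen_fp_direct, gen_itc, gen_pulldown


def _standard_experiment(cell=28e-6, syringe=0.30e-3, v0=200e-6):
    return binding.ItcExperiment(cell, syringe, v0,
                                 binding.standard_injection_scheme())


class TestItcIsotherm:
    def test_saturation_limit_total_heat(self):
        # ideal geometry: total heat approaches N Mt V0 dH at saturation
        exp = binding.ItcExperiment(1e-6, 5e-3, 200e-6, np.full(40, 1e-6),
                                    pre_injection=False)
        heats = binding.itc_isotherm(1.0, 1e-12, -10.0, exp, volume_correction="none")
        total_cal = heats.sum() * 1e-6
        expected = 1.0 * 1e-6 * 200e-6 * (-10.0 * 1000)
        assert total_cal == pytest.approx(expected, rel=1e-6)

    def test_infinite_kd_no_heat(self):
        exp = _standard_experiment()
        heats = binding.itc_isotherm(1.0, 1e3, -10.0, exp)
        assert np.max(np.abs(heats)) < 1e-3  # ucal

    def test_matches_root_finder_oracle(self):
        n, kd, dh = 0.97, 67e-9, -10.0
        exp = _standard_experiment()
        dv = exp.injection_volumes
        vcum = np.cumsum(dv)
        d = vcum / exp.cell_volume
        mt = exp.cell_concentration * (1 - d / 2) / (1 + d / 2)
        xt = exp.syringe_concentration * d / (1 + d / 2)
        q_model = binding._wiseman_cumulative_heat(n, kd, dh, mt, xt, exp.cell_volume)
        for i in range(len(dv)):
            theta = binding.bound_fraction_root(n, kd, float(mt[i]), float(xt[i]))
            q_oracle = n * theta * mt[i] * exp.cell_volume * dh * 1000
            assert abs(q_model[i] - q_oracle) <= 1e-9 * abs(q_oracle)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            binding.itc_isotherm(0.0, 1e-7, -10.0, _standard_experiment())


class TestFitItc:
    def test_noiseless_xph20_grade_affinity_recovered(self):
        exp, truth = gen_itc(seed=0, kd=67e-9)
        fit = binding.fit_itc(exp)
        assert fit.kd == pytest.approx(67e-9, rel=5e-3)
        assert fit.n == pytest.approx(1.0, rel=5e-3)
        assert fit.dh_kcal == pytest.approx(-10.0, rel=5e-3)

    def test_unity_stoichiometry_recovered_over_draws(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            kd = 10 ** rng.uniform(-8.5, -6)
            dh = rng.uniform(-15, -5)
            exp, _ = gen_itc(seed=0, kd=kd, dh_kcal=dh)
            fit = binding.fit_itc(exp)
            assert fit.n == pytest.approx(1.0, rel=1e-3)

    def test_noisy_kd_within_band(self):
        exp, truth = gen_itc(seed=9, noise_fraction=0.02)
        fit = binding.fit_itc(exp)
        assert fit.kd == pytest.approx(truth["kd"], rel=0.30)

    def test_low_c_value_warns_not_fails(self):
        # c = N Mt / KD ~ 0.05: hopelessly shallow isotherm
        exp, _ = gen_itc(seed=0, kd=5e-4, cell_concentration=25e-6,
                         syringe_concentration=20e-3)
        with pytest.warns(UserWarning, match="c value"):
            fit = binding.fit_itc(exp)
        assert fit.unreliable_c

    def test_too_few_injections_rejected(self):
        exp = binding.ItcExperiment(28e-6, 3e-4, 200e-6, np.full(5, 1e-6),
                                    heats_ucal=np.zeros(5))
        with pytest.raises(ValueError):
            binding.fit_itc(exp)


class TestFpDirect:
    def test_low_tracer_limit_is_hyperbola(self):
        kd, lt = 1e-6, 1e-12
        rt = np.geomspace(1e-8, 1e-4, 20)
        fb = binding.fp_bound_fraction(kd, rt, lt)
        assert np.allclose(fb, rt / (rt + kd), rtol=1e-4)

    def test_saturating_receptor_binds_all_tracer(self):
        fb = binding.fp_bound_fraction(1e-6, np.array([1.0]), 50e-9)
        assert fb[0] == pytest.approx(1.0, rel=1e-5)

    def test_matches_mass_balance_solver_on_grid(self):
        for kd in (1e-8, 1e-6, 1e-4):
            for lt in (1e-9, 5e-8, 1e-6):
                for rt in (1e-9, 1e-7, 1e-5, 1e-3):
                    fb = float(binding.fp_bound_fraction(kd, np.array([rt]), lt)[0])
                    def f(x):  # x = bound tracer
                        return (lt - x) * (rt - x) - kd * x
                    bound = brentq(f, 0.0, min(lt, rt), xtol=1e-30, rtol=1e-15)
                    assert abs(fb - bound / lt) < 1e-10

    def test_fit_recovers_planted_kd(self):
        tit, truth = gen_fp_direct(seed=3)
        fit = binding.fp_direct_fit(tit)
        assert fit.kd == pytest.approx(truth["kd"], rel=1e-3)

    def test_gross_non_monotone_warns(self):
        tit, _ = gen_fp_direct(seed=3)
        tit.polarization_mp = tit.polarization_mp[::-1].copy()
        with pytest.warns(UserWarning, match="non-monotonicity"):
            binding.fp_direct_fit(tit)


class TestCompetition:
    def test_zero_competitor_reduces_to_direct_binding(self):
        rt, lt, kdl = 2e-6, 50e-9, 1e-6
        fb = binding.tracer_bound_fraction_competition(rt, lt, np.array([0.0]),
                                                       kdl, 1e-6)
        direct = binding.fp_bound_fraction(kdl, np.array([rt]), lt)
        assert fb[0] == pytest.approx(float(direct[0]), rel=1e-9)

    def test_cubic_matches_iterative_solver(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            rt, lt, it = (10 ** rng.uniform(-9, -4) for _ in range(3))
            kdl, ki = (10 ** rng.uniform(-10, -4) for _ in range(2))
            r = binding.free_receptor_ternary(rt, lt, it, kdl, ki)
            oracle = brentq(lambda R: R * (1 + lt / (kdl + R) + it / (ki + R)) - rt,
                            0.0, rt, xtol=1e-30, rtol=1e-15)
            assert abs(r - oracle) <= 1e-9 * oracle

    def test_weak_competitor_leaves_signal_flat(self):
        # monotonicity in KI: stronger KI (larger) -> closer to no-competitor signal
        rt, lt, kdl = 2e-6, 50e-9, 1e-6
        it = np.geomspace(1e-9, 1e-3, 10)
        f_none = binding.fp_bound_fraction(kdl, np.array([rt]), lt)[0]
        prev = None
        for ki in (1e-8, 1e-6, 1e-4, 1e-2):
            fb = binding.tracer_bound_fraction_competition(rt, lt, it, kdl, ki)
            if prev is not None:
                assert np.all(fb >= prev - 1e-12)
            prev = fb
        assert np.allclose(
            binding.tracer_bound_fraction_competition(rt, lt, it, kdl, 1e3),
            f_none, rtol=1e-3)

    def test_planted_ki_recovered_with_noise(self):
        curve, truth = gen_fp_competition(seed=13, noise_mp=1.0)
        fit = binding.fp_competition_ki(curve)
        assert fit.ki == pytest.approx(truth["ki"], rel=0.20)
        assert not fit.lower_bound_only

    def test_flat_curve_flagged_lower_bound(self):
        curve, _ = gen_fp_competition(seed=13, ki=1.0e-1, noise_mp=1.0)
        fit = binding.fp_competition_ki(curve)
        assert fit.lower_bound_only


class TestPulldown:
    def test_cheng_prusoff_midpoint_algebra(self):
        # [tracer] = KD_tracer ties IC50 to 2 KI on the fitted model
        ki, kdt, lt = 1e-6, 5e-7, 5e-7
        ic50 = ki * (1 + lt / kdt)
        assert ic50 == pytest.approx(2 * ki)

    def test_vanishing_tracer_ic50_equals_ki(self):
        ki, kdt = 1e-6, 5e-7
        assert ki * (1 + 1e-12 / kdt) == pytest.approx(ki, rel=1e-5)

    def test_planted_ki_within_twofold(self):
        curve, truth = gen_pulldown(seed=21, noise_fraction=0.05)
        fit = binding.pulldown_ki(curve)
        assert truth["ki"] / 2 <= fit.ki <= truth["ki"] * 2

    def test_too_few_levels_rejected(self):
        curve = binding.CompetitionCurve(
            np.array([0.0, 1e-7, 1e-6]), np.array([100.0, 70.0, 30.0]),
            receptor_total=1e-6, tracer_total=5e-7, tracer_kd=5e-7)
        with pytest.raises(ValueError):
            binding.pulldown_ki(curve)


class TestEffectiveConcentration:
    def test_identity_case(self):
        assert binding.effective_concentration(1e-6, 1e-6, 1e-6) == pytest.approx(1e-6)

    def test_thousandfold_gain(self):
        assert binding.effective_concentration(1e-6, 1e-6, 1e-9) == pytest.approx(1e-3)

    def test_module_scale_yields_tens_of_millimolar(self):
        # monobody and peptide modules in the 1e-7..1e-6 M range fused into a
        # subnanomolar binder land in the 10-50 mM effective-concentration band
        c_eff = binding.effective_concentration(330e-9, 1e-6, 1e-11)
        assert 10e-3 <= c_eff <= 50e-3

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            binding.effective_concentration(1e-6, 0.0, 1e-9)
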