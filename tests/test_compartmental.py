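import numpy as np
import pytest
from scipy.integrate import quad

from noncanon_pk.compartmental import (
    FitResult,
    MacroConstants,
    Model,
    Weighting,
    fit_decay,
    hybrid_auc_inf,
    hybrid_aumc_inf,
    model_tail_auc,
    model_tail_aumc,
    predict,
    select_model,
    strip_estimates,
)
from noncanon_pk.simulate import add_noise
from helpers import make_profile


class TestPredict:
    def test_mono_intercept(self):
        m = MacroConstants(A=0, B=42.0, alpha=0.0, beta=0.1)
        assert predict(m, 0.0) == pytest.approx(42.0)

    def test_decay_limit(self, rabbit_like_macro):
        assert predict(rabbit_like_macro, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_independent_arithmetic(self):
        m = MacroConstants(A=100, B=50, alpha=0.2, beta=0.03)
        expected = 100 * np.exp(-2.0) + 50 * np.exp(-0.3)
        assert predict(m, 10.0) == pytest.approx(expected, rel=1e-12)


class TestStripEstimates:
    def test_recovers_known_constants(self):
        truth = MacroConstants(A=300, B=150, alpha=0.25, beta=0.03)
        t = np.arange(4.0, 31.0, 2.0)
        p = make_profile(t, predict(truth, t))
        est = strip_estimates(p, t_start=4.0, n_terminal=4)
        for name in ("A", "B", "alpha", "beta"):
            assert getattr(est, name) == pytest.approx(getattr(truth, name), rel=0.05)

    def test_mono_data_gives_mono_estimate(self):
        t = np.arange(4.0, 31.0, 2.0)
        p = make_profile(t, 80 * np.exp(-0.05 * t))
        est = strip_estimates(p, 4.0)
        assert est.B * np.exp(-est.beta * t[0]) == pytest.approx(p.concentrations[0], rel=1e-6)

    def test_zero_concentration_excluded(self):
        t = np.array([4.0, 6.0, 10.0, 20.0, 30.0])
        c = np.array([100.0, 60.0, 30.0, 5.0, 0.0])
        est = strip_estimates(make_profile(t, c), 4.0)  # must not raise on log(0)
        assert est.beta > 0

    def test_too_few_points_errors(self):
        p = make_profile([4.0], [10.0])
        with pytest.raises(ValueError):
            strip_estimates(p, 4.0)


class TestFitDecay:
    def test_noiseless_biexponential_recovery(self, rabbit_like_macro, dense_schedule):
        t = dense_schedule[dense_schedule >= 4]
        p = make_profile(t, predict(rabbit_like_macro, t))
        fit = fit_decay(p, Model.BI, t_start=4.0)
        for name in ("A", "B", "alpha", "beta"):
            assert getattr(fit.macro, name) == pytest.approx(
                getattr(rabbit_like_macro, name), rel=1e-6
            )

    def test_mono_on_mono_data(self):
        t = np.arange(4.0, 121.0, 10.0)
        p = make_profile(t, 120 * np.exp(-0.03 * t))
        fit = fit_decay(p, Model.MONO, t_start=4.0)
        assert fit.macro.B == pytest.approx(120, rel=1e-8)
        assert fit.macro.beta == pytest.approx(0.03, rel=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weighting", list(Weighting))
    def test_weightings_agree_on_noiseless_data(self, weighting, rabbit_like_macro, dense_schedule):
        p = make_profile(dense_schedule, predict(rabbit_like_macro, dense_schedule))
        fit = fit_decay(p, Model.BI, t_start=4.0, weighting=weighting)
        assert fit.macro.beta == pytest.approx(rabbit_like_macro.beta, rel=1e-5)

    def test_montecarlo_beta_bias_small(self, dense_schedule):
        """10% lognormal noise, rabbit-like truth: median relative bias of β < 5%."""
        truth = MacroConstants(A=400, B=180, alpha=0.5, beta=0.035)
        t = dense_schedule
        clean = make_profile(t, predict(truth, t))
        betas = []
        for seed in range(200):
            noisy = add_noise(clean, cv=0.10, n_animals=3, seed=seed)
            fit = fit_decay(noisy, Model.BI, t_start=4.0)
            betas.append(fit.macro.beta)
        median_bias = abs(np.median(betas) - truth.beta) / truth.beta
        assert median_bias < 0.05

    def test_excluding_all_points_errors(self, biexp_profile):
        with pytest.raises(ValueError):
            fit_decay(biexp_profile, Model.BI, t_start=1000.0)

    def test_scale_equivariance(self, rabbit_like_macro, dense_schedule):
        p = make_profile(dense_schedule, predict(rabbit_like_macro, dense_schedule))
        k = 3.7
        fit1 = fit_decay(p, Model.BI, t_start=4.0)
        fit2 = fit_decay(p.scaled(k), Model.BI, t_start=4.0)
        assert fit2.macro.A == pytest.approx(k * fit1.macro.A, rel=1e-6)
        assert fit2.macro.B == pytest.approx(k * fit1.macro.B, rel=1e-6)
        assert fit2.macro.alpha == pytest.approx(fit1.macro.alpha, rel=1e-6)
        assert fit2.macro.beta == pytest.approx(fit1.macro.beta, rel=1e-6)

    def test_time_unit_coherence(self, rabbit_like_macro, dense_schedule):
        """Refitting with times in hours scales α, β by 60."""
        p_min = make_profile(dense_schedule, predict(rabbit_like_macro, dense_schedule))
        p_hr = make_profile(dense_schedule / 60.0, p_min.concentrations)
        fit_min = fit_decay(p_min, Model.BI, t_start=4.0)
        fit_hr = fit_decay(p_hr, Model.BI, t_start=4.0 / 60.0)
        assert fit_hr.macro.alpha == pytest.approx(60 * fit_min.macro.alpha, rel=1e-5)
        assert fit_hr.macro.beta == pytest.approx(60 * fit_min.macro.beta, rel=1e-5)


class TestSelectModel:
    def _fits(self, macro, t):
        p = make_profile(t, predict(macro, t))
        return fit_decay(p, Model.MONO, t_start=float(t[0])), fit_decay(
            p, Model.BI, t_start=float(t[0])
        )

    def test_separated_phases_select_bi(self, dense_schedule):
        truth = MacroConstants(A=300, B=100, alpha=0.3, beta=0.03)  # α/β = 10
        fm, fb = self._fits(truth, dense_schedule)
        assert select_model(fm, fb) is Model.BI

    def test_single_exponential_selects_mono(self, dense_schedule):
        t = dense_schedule
        p = make_profile(t, 100 * np.exp(-0.05 * t))
        fm = fit_decay(p, Model.MONO, t_start=2.0)
        fb = fit_decay(p, Model.BI, t_start=2.0)
        assert select_model(fm, fb) is Model.MONO

    def test_tie_goes_to_mono(self, biexp_profile):
        fm = fit_decay(biexp_profile, Model.MONO, t_start=4.0)
        tied = FitResult(
            model=Model.BI, macro=fm.macro, t_start=fm.t_start,
            rss=fm.rss, n_points=fm.n_points, aicc=fm.aicc, weighting=fm.weighting,
        )
        assert select_model(fm, tied) is Model.MONO

    def test_mismatched_data_errors(self, dense_schedule):
        truth = MacroConstants(A=300, B=100, alpha=0.3, beta=0.03)
        fm, _ = self._fits(truth, dense_schedule)
        _, fb = self._fits(truth, dense_schedule[1:])
        with pytest.raises(ValueError):
            select_model(fm, fb)

    def test_bi_probability_grows_with_separation(self):
        """At fixed noise, bi is picked more often when α/β = 10 than 1.5."""
        t = np.array([2.0, 4.0, 6.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0])
        picks = {}
        for ratio in (1.5, 10.0):
            truth = MacroConstants(A=300, B=100, alpha=0.035 * ratio, beta=0.035)
            clean = make_profile(t, predict(truth, t))
            n_bi = 0
            for seed in range(100):
                noisy = add_noise(clean, cv=0.05, n_animals=6, seed=seed)
                fm = fit_decay(noisy, Model.MONO, t_start=2.0)
                fb = fit_decay(noisy, Model.BI, t_start=2.0)
                n_bi += select_model(fm, fb) is Model.BI
            picks[ratio] = n_bi
        assert picks[10.0] > picks[1.5]
        assert picks[10.0] >= 90


class TestTailIntegrals:
    def test_full_integral_at_zero(self, rabbit_like_macro):
        m = rabbit_like_macro
        assert model_tail_auc(m, 0.0) == pytest.approx(m.A / m.alpha + m.B / m.beta)
        assert model_tail_aumc(m, 0.0) == pytest.approx(m.A / m.alpha**2 + m.B / m.beta**2)

    def test_vanishes_at_infinity(self, rabbit_like_macro):
        assert model_tail_auc(rabbit_like_macro, 1e5) == pytest.approx(0.0, abs=1e-12)

    def test_mono_tail(self):
        m = MacroConstants(A=0, B=80, alpha=0.0, beta=0.04)
        assert model_tail_aumc(m, 0.0) == pytest.approx(80 / 0.04**2)

    def test_matches_quadrature(self, rabbit_like_macro):
        m, t_star = rabbit_like_macro, 4.0
        q_auc, _ = quad(lambda t: predict(m, t), t_star, 1e5, limit=400)
        q_aumc, _ = quad(lambda t: t * predict(m, t), t_star, 1e5, limit=400)
        assert model_tail_auc(m, t_star) == pytest.approx(q_auc, rel=1e-6)
        assert model_tail_aumc(m, t_star) == pytest.approx(q_aumc, rel=1e-6)


class TestHybridAuc:
    def test_model_exact_data_equals_analytic(self, rabbit_like_macro):
        """On model-exact samples, hybrid AUC = analytic integral within trapezoid error."""
        m = rabbit_like_macro
        t = np.arange(2.0, 120.5, 2.0)
        p = make_profile(t, predict(m, t))
        fit = fit_decay(p, Model.BI, t_start=4.0)
        analytic = model_tail_auc(m, 2.0)  # ∫_{t_first}^∞
        h = 2.0
        max_c2 = m.A * m.alpha**2 + m.B * m.beta**2  # |c″| at t=0 bounds [2,4]
        bound = (4.0 - 2.0) * h**2 * max_c2 / 12
        assert abs(hybrid_auc_inf(p, fit, t_split=4.0) - analytic) <= bound + 1e-9

    def test_split_at_first_observation_is_pure_tail(self, biexp_profile, rabbit_like_macro):
        fit = fit_decay(biexp_profile, Model.BI, t_start=4.0)
        expected = model_tail_auc(fit.macro, 2.0)
        assert hybrid_auc_inf(biexp_profile, fit, t_split=2.0) == pytest.approx(expected)

    def test_doubling_concentrations_doubles_auc(self, biexp_profile):
        fit1 = fit_decay(biexp_profile, Model.BI, t_start=4.0)
        doubled = biexp_profile.scaled(2.0)
        fit2 = fit_decay(doubled, Model.BI, t_start=4.0)
        a1 = hybrid_auc_inf(biexp_profile, fit1)
        a2 = hybrid_auc_inf(doubled, fit2)
        assert a2 == pytest.approx(2 * a1, rel=1e-6)

    def test_hybrid_aumc_on_model_exact_data(self, rabbit_like_macro):
        m = rabbit_like_macro
        t = np.arange(2.0, 120.5, 0.5)
        p = make_profile(t, predict(m, t))
        fit = fit_decay(p, Model.BI, t_start=4.0)
        analytic = model_tail_aumc(m, 2.0)
        assert hybrid_aumc_inf(p, fit, t_split=4.0) == pytest.approx(analytic, rel=1e-4)
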