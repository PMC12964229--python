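"""Parametric families, ML fitting, splines, model averaging, medians."""

import numpy as np
import pytest

from psmcea import (ArmSpec, simulate_arm, evaluate_survival, fit_parametric,
                    fit_spline, from_coefficients, ic_weights, median_survival,
                    model_average, survival_function, NotReached)
from psmcea.survival import FAMILIES

ECF_OS = from_coefficients("llogis", [3.32042, 0.52871])
SOC_OS = from_coefficients("gamma", [-2.36584, 0.60967])


class TestEvaluateSurvival:
    @pytest.mark.parametrize("family,coefs", [
        ("exponential", [-2.3]), ("weibull", [0.2, 2.5]),
        ("gompertz", [0.05, -2.5]), ("llogis", [3.32042, 0.52871]),
        ("lnorm", [2.0, -0.05]), ("gamma", [-2.36584, 0.60967]),
        ("gengamma", [2.0, 0.1, 0.5]),
    ])
    def test_survival_starts_at_one_and_is_monotone(self, family, coefs):
        fit = from_coefficients(family, coefs)
        grid = np.linspace(0, 360, 721)
        s = evaluate_survival(fit, grid)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert s[-1] < evaluate_survival(fit, np.array([12.0]))[0]

    def test_loglogistic_median_equals_natural_scale_parameter(self):
        # S(exp(scale-coef)) = 0.5 for the log-logistic
        t_med = np.exp(3.32042)
        assert evaluate_survival(ECF_OS, np.array([t_med]))[0] == pytest.approx(0.5)
        assert median_survival(survival_function(ECF_OS)) == pytest.approx(
            t_med, abs=1e-4)

    def test_gamma_os_consistent_with_trial_median(self):
        # chemotherapy-arm OS model: survival near 0.5 at the 15.1-month
        # trial median
        s = evaluate_survival(SOC_OS, np.array([15.1]))[0]
        assert 0.45 < s < 0.55

    def test_negative_time_and_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            evaluate_survival(ECF_OS, np.array([-1.0]))
        with pytest.raises(ValueError, match="unknown survival family"):
            from_coefficients("nosuch", [1.0])


class TestFitParametric:
    def test_exponential_mle_matches_closed_form(self):
        ipd = simulate_arm(ArmSpec("A", "OS", "exponential", (0.1,), 2000,
                                   cutoff_months=1e9, seed=7))
        fit = fit_parametric(ipd.times, ipd.events, "exponential")
        # closed-form MLE d / sum(t) on the log scale
        closed = np.log(ipd.events.sum() / ipd.times.sum())
        assert fit.coefs[0] == pytest.approx(closed, abs=1e-5)
        se = np.sqrt(fit.vcov[0, 0])
        assert abs(fit.coefs[0] - np.log(0.1)) < 3 * se

    def test_all_censored_data_rejected(self):
        with pytest.raises(ValueError, match="all-censored"):
            fit_parametric([1.0, 2.0], [0, 0], "exponential")

    def test_information_criteria_identities(self):
        ipd = simulate_arm(ArmSpec("A", "OS", "weibull", (1.3, 12.0), 500,
                                   cutoff_months=60, seed=3))
        fit = fit_parametric(ipd.times, ipd.events, "weibull")
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)
        assert fit.bic == pytest.approx(2 * np.log(500) - 2 * fit.loglik)

    def test_weibull_fit_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        ipd = simulate_arm(ArmSpec("A", "OS", "weibull", (1.4, 15.0), 800,
                                   cutoff_months=48, dropout_rate_per_month=0.01,
                                   seed=13))
        fit = fit_parametric(ipd.times, ipd.events, "weibull")
        wf = lifelines.WeibullFitter().fit(ipd.times, ipd.events)
        shape, scale = FAMILIES["weibull"].to_natural(fit.coefs)
        assert shape == pytest.approx(wf.rho_, rel=1e-3)
        assert scale == pytest.approx(wf.lambda_, rel=1e-3)
        assert fit.loglik == pytest.approx(wf.log_likelihood_, abs=1e-3)

    @pytest.mark.parametrize("family,params", [
        ("exponential", (0.09,)),
        ("weibull", (1.4, 14.0)),
        ("llogis", (13.7, 1.75)),
        ("lnorm", (2.3, 0.9)),
        ("gamma", (0.094, 1.84)),
        ("gompertz", (0.04, 0.05)),
    ])
    def test_parameter_recovery_within_three_se(self, family, params):
        """Fitting data simulated from the family itself recovers every
        coefficient within 3 SE in nearly all seeded replicates."""
        truth = np.asarray(FAMILIES[family].to_estimation(params))
        n_rep, hits = 12, 0
        for rep in range(n_rep):
            ipd = simulate_arm(ArmSpec("A", "OS", family, params, 2000,
                                       cutoff_months=1e9, seed=100 + rep))
            fit = fit_parametric(ipd.times, ipd.events, family)
            se = np.sqrt(np.diag(fit.vcov))
            hits += int(np.all(np.abs(fit.coefs - truth) <= 3 * se))
        assert hits >= n_rep - 1

    def test_aic_prefers_parsimony_on_nested_truth(self):
        # exponential truth: gen-gamma's AIC pays ~2 per extra parameter
        diffs = []
        for rep in range(20):
            ipd = simulate_arm(ArmSpec("A", "OS", "exponential", (0.1,), 400,
                                       cutoff_months=1e9, seed=300 + rep))
            fe = fit_parametric(ipd.times, ipd.events, "exponential")
            fg = fit_parametric(ipd.times, ipd.events, "gengamma")
            diffs.append(fg.aic - fe.aic)
        assert np.mean(diffs) > 0
        assert np.mean(diffs) < 2 * 2 + 2  # within ~2 per extra parameter


@pytest.fixture(scope="module")
def weib_ipd():
    return simulate_arm(ArmSpec("A", "OS", "weibull", (1.5, 12.0), 1000,
                                cutoff_months=60, dropout_rate_per_month=0.005,
                                seed=21))


class TestFitSpline:
    def test_zero_knot_limit_equals_weibull_loglik(self, weib_ipd):
        wb = fit_parametric(weib_ipd.times, weib_ipd.events, "weibull")
        sp = fit_spline(weib_ipd.times, weib_ipd.events, 0)
        assert sp.loglik == pytest.approx(wb.loglik, abs=1e-6)

    def test_nesting_improves_loglik(self, weib_ipd):
        lls = [fit_spline(weib_ipd.times, weib_ipd.events, k).loglik
               for k in (0, 1, 2)]
        assert lls[0] <= lls[1] + 1e-6
        assert lls[1] <= lls[2] + 1e-6

    def test_two_knot_fit_tracks_generating_curve(self, weib_ipd):
        sp = fit_spline(weib_ipd.times, weib_ipd.events, 2)
        truth = from_coefficients("weibull",
                                  FAMILIES["weibull"].to_estimation((1.5, 12.0)))
        for q in (0.25, 0.5, 0.75):
            t_q = 12.0 * (-np.log(q)) ** (1 / 1.5)  # Weibull quantile
            assert evaluate_survival(sp, np.array([t_q]))[0] == pytest.approx(
                evaluate_survival(truth, np.array([t_q]))[0], abs=0.03)

    def test_invalid_knot_count_rejected(self, weib_ipd):
        with pytest.raises(ValueError, match="knots"):
            fit_spline(weib_ipd.times, weib_ipd.events, 4)


class TestModelAverage:
    def test_equal_ic_gives_equal_weights(self):
        assert np.allclose(ic_weights([100.0, 100.0]), [0.5, 0.5])

    def test_large_delta_gives_negligible_weight(self):
        w = ic_weights([10.0, 30.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-10)), abs=1e-9)
        assert w[1] == pytest.approx(np.exp(-10) / (1 + np.exp(-10)), rel=1e-6)

    def test_weights_sum_to_one_and_are_permutation_invariant(self):
        ics = [210.3, 204.4, 207.9]
        w = ic_weights(ics)
        assert np.sum(w) == pytest.approx(1.0)
        assert np.allclose(ic_weights(ics[::-1]), w[::-1])

    def test_average_preserves_unit_start_and_rejects_mixed_data(self, exp_arm):
        f1 = fit_parametric(exp_arm.times, exp_arm.events, "exponential")
        f2 = fit_parametric(exp_arm.times, exp_arm.events, "weibull")
        avg = model_average([f1, f2], "AIC")
        assert avg(np.array([0.0]))[0] == 1.0
        other = simulate_arm(ArmSpec("B", "OS", "exponential", (0.2,), 100,
                                     cutoff_months=1e9, seed=2))
        f3 = fit_parametric(other.times, other.events, "exponential")
        with pytest.raises(ValueError, match="different data"):
            model_average([f1, f3])


class TestMedianSurvival:
    def test_exponential_closed_form(self):
        fit = from_coefficients("exponential", [np.log(0.1)])
        assert median_survival(survival_function(fit)) == pytest.approx(
            np.log(2) / 0.1, abs=1e-5)

    def test_combination_pfs_median_matches_trial_scale(self):
        fit = from_coefficients("llogis", [2.61476, 0.56027])
        med = median_survival(survival_function(fit))
        assert med == pytest.approx(np.exp(2.61476), abs=1e-4)  # ~13.66 months

    def test_flat_curve_reports_not_reached(self):
        from psmcea.survival import SurvivalFunction
        flat = SurvivalFunction(fn=lambda t: np.ones_like(np.asarray(t, float)))
        assert isinstance(median_survival(flat), NotReached)
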