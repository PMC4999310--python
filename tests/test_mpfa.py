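"""MPFA: pairwise variance, weighting, parabola fit, failure rates."""

import warnings

import numpy as np
import pytest

from synquant import mpfa, simulate
from synquant.types import QuantalParameters, VarianceMeanPoint


def make_points(means, variances, n=75, labels=None):
    labels = labels or [f"c{i}" for i in range(len(means))]
    return [
        VarianceMeanPoint(m, v, n, 1.0 / mpfa.variance_of_variance(v, n),
                          condition_label=lab)
        for m, v, lab in zip(means, variances, labels)
    ]


class TestPairwiseVariance:
    def test_constant_sequence_zero(self):
        assert mpfa.pairwise_variance([5.0, 5.0, 5.0, 5.0]) == 0.0

    def test_alternating_sequence(self):
        # diffs (2,-2,2): sum of squares 12, / (2*3) = 2
        assert mpfa.pairwise_variance([1.0, 3.0, 1.0, 3.0]) == 2.0

    def test_iid_equivalence_with_sample_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 3.0, 10000)
        pv = mpfa.pairwise_variance(x)
        assert pv == pytest.approx(9.0, rel=0.05)
        assert pv == pytest.approx(np.var(x, ddof=1), rel=0.03)

    def test_linear_ramp_gives_half_step_squared(self):
        # drift robustness: ramp a + b*i contributes exactly b^2/2
        for n in (10, 100, 1000):
            b = 0.7
            x = 3.0 + b * np.arange(n)
            assert mpfa.pairwise_variance(x) == pytest.approx(b**2 / 2)
            assert np.var(x, ddof=1) > 10 * mpfa.pairwise_variance(x)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mpfa.pairwise_variance([1.0])


class TestVarianceOfVariance:
    def test_closed_form_values(self):
        assert mpfa.variance_of_variance(10.0, 101) == pytest.approx(2.0)
        assert mpfa.variance_of_variance(7.0, 2) == pytest.approx(2 * 49.0)

    def test_monte_carlo_sampling_variance_of_pairwise_estimator(self):
        # exact oracle for iid Gaussian data: consecutive differences
        # d_i ~ N(0, 2s^2) with cov(d_i, d_{i+1}) = -s^2 give
        # Var(s^2_pw) = s^4 * (3n - 4) / (n - 1)^2
        rng = np.random.default_rng(5)
        sigma2, n = 4.0, 75
        estimates = [
            mpfa.pairwise_variance(rng.normal(0, 2.0, n))
            for _ in range(10000)
        ]
        exact = sigma2**2 * (3 * n - 4) / (n - 1) ** 2
        assert np.var(estimates, ddof=1) == pytest.approx(exact, rel=0.10)
        # the Gaussian 2*sigma^4/(n-1) weighting formula understates this
        # by a constant factor ~1.5; as a WLS weight only proportionality
        # matters, and both scale as sigma^4
        ratio = exact / mpfa.variance_of_variance(sigma2, n)
        assert ratio == pytest.approx(1.5, abs=0.02)


class TestVarianceMeanPoints:
    def test_means_match_theory(self, human_like_params, conditions):
        exp = simulate.make_experiment(human_like_params, conditions, 75,
                                       seed=17)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            points = mpfa.variance_mean_points(exp, require_stability=False)
        assert len(points) == 4
        for pt, cond in zip(points, conditions):
            mean, var, _ = simulate.theoretical_moments(human_like_params,
                                                        cond.p_r)
            se = np.sqrt(var / pt.n_trials)
            assert abs(pt.mean_fc - mean) < 3 * se

    def test_degenerate_constant_epochs_flagged(self, human_like_params,
                                                conditions):
        exp = simulate.make_experiment(human_like_params,
                                       [c.__class__(c.label, c.ca_mM, 1.0)
                                        for c in conditions],
                                       20, seed=1)
        points = mpfa.variance_mean_points(exp)
        assert all(p.degenerate and p.pairwise_variance_fc2 == 0.0
                   for p in points)

    def test_two_epoch_experiment_rejected(self, human_like_params,
                                           conditions):
        exp = simulate.make_experiment(human_like_params, conditions, 40,
                                       seed=2)
        exp.epochs = exp.epochs[:2]
        with pytest.raises(ValueError, match="3 conditions"):
            mpfa.variance_mean_points(exp)


class TestFitParabola:
    def test_exact_recovery_from_noiseless_points(self):
        # theoretical (mean, variance) of q=40, N=20 at the P_r grid
        means = [80.0, 264.0, 400.0, 640.0]
        variances = [2880.0, 7075.2, 8000.0, 5120.0]
        fit = mpfa.fit_parabola(make_points(means, variances))
        assert fit.q_fc == pytest.approx(40.0, rel=1e-9)
        assert fit.n_frs == pytest.approx(20.0, rel=1e-9)
        for label, p in zip(("c0", "c1", "c2", "c3"),
                            (0.1, 0.33, 0.5, 0.8)):
            assert fit.p_r_by_condition[label] == pytest.approx(p, rel=1e-9)

    def test_parameter_recovery_100_experiments(self, human_like_params,
                                                conditions):
        qs, ns = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(1, 101):
                exp = simulate.make_experiment(human_like_params, conditions,
                                               75, seed=seed)
                pts = mpfa.variance_mean_points(exp, require_stability=False)
                fit = mpfa.fit_parabola(pts)
                if fit.n_frs is not None:
                    qs.append(fit.q_fc)
                    ns.append(fit.n_frs)
        assert len(qs) >= 90
        assert np.median(ns) == pytest.approx(20.0, rel=0.20)
        assert np.median(qs) == pytest.approx(40.0, rel=0.10)

    def test_collinear_points_report_no_curvature(self):
        means = [100.0, 200.0, 300.0]
        variances = [30.0 * m for m in means]
        fit = mpfa.fit_parabola(make_points(means, variances))
        assert fit.n_frs is None
        assert not fit.converged
        assert any("no curvature" in w for w in fit.warnings)
        assert fit.q_fc == pytest.approx(30.0, rel=1e-6)

    def test_duplicate_means_rejected(self):
        pts = make_points([100.0, 100.0, 300.0], [50.0, 60.0, 70.0])
        with pytest.raises(ValueError, match="duplicate"):
            mpfa.fit_parabola(pts)

    def test_scale_equivariance(self):
        means = np.array([80.0, 264.0, 400.0, 640.0])
        variances = np.array([2880.0, 7075.2, 8000.0, 5120.0])
        f1 = mpfa.fit_parabola(make_points(means, variances))
        c = 2.5  # charges scaled by c: means by c, variances by c^2
        f2 = mpfa.fit_parabola(make_points(means * c, variances * c**2))
        assert f2.q_fc == pytest.approx(c * f1.q_fc, rel=1e-9)
        assert f2.n_frs == pytest.approx(f1.n_frs, rel=1e-9)
        for k in f1.p_r_by_condition:
            assert f2.p_r_by_condition[k] == pytest.approx(
                f1.p_r_by_condition[k], rel=1e-9)

    def test_p_r_monotone_in_mean(self):
        means = [80.0, 264.0, 400.0, 640.0]
        variances = [2880.0, 7075.2, 8000.0, 5120.0]
        fit = mpfa.fit_parabola(make_points(means, variances))
        prs = [fit.p_r_by_condition[f"c{i}"] for i in range(4)]
        assert all(b > a for a, b in zip(prs, prs[1:]))

    def test_q_inflation_under_intra_site_variability(self, conditions):
        # with cv_intra the parabola slope estimates q*(1 + cv^2):
        # expected inflation 1.09 at cv = 0.3
        params = QuantalParameters(n_sites=20, q_fc=40.0, cv_intra=0.3)
        inflation = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(60):
                exp = simulate.make_experiment(params, conditions, 400,
                                               seed=seed)
                pts = mpfa.variance_mean_points(exp, require_stability=False)
                fit = mpfa.fit_parabola(pts)
                inflation.append(fit.q_fc / 40.0)
        assert 1.04 < np.median(inflation) < 1.14


class TestFailureRates:
    def test_closed_form_values(self):
        assert mpfa.predicted_failure_rate(1.0, 0.0) == 1.0
        assert mpfa.predicted_failure_rate(1.0, 0.3) == pytest.approx(0.7)
        assert mpfa.predicted_failure_rate(5.0, 0.2) == pytest.approx(0.32768)

    def test_matches_simulation(self):
        p = QuantalParameters(n_sites=5, q_fc=10.0)
        x = simulate.simulate_trial_charges(p, 0.2, 100000, seed=21)
        predicted = mpfa.predicted_failure_rate(5, 0.2)
        se = np.sqrt(predicted * (1 - predicted) / len(x))
        assert abs((x == 0).mean() - predicted) < 3 * se

    def test_rat_like_prediction_consistent_with_observation(self):
        # rat-like fit at 1.5 mM Ca: N = 4.7, P_r = 0.17 predicts ~0.417
        fit = mpfa.MPFAFit(q_fc=30.0, n_frs=4.7, coeff_a=30.0,
                           coeff_b=1 / 4.7,
                           p_r_by_condition={"ca1.5": 0.17})
        predicted = mpfa.predicted_failure_rate(4.7, 0.17)
        assert predicted == pytest.approx(0.417, abs=0.005)
        report = mpfa.failure_consistency(fit, {"ca1.5": 0.391},
                                          {"ca1.5": 75})
        assert not report[0]["flagged"]
        assert report[0]["n_se"] < 1.0

    def test_certain_release_with_failures_flagged(self):
        fit = mpfa.MPFAFit(q_fc=30.0, n_frs=5.0, coeff_a=30.0, coeff_b=0.2,
                           p_r_by_condition={"hi": 1.0})
        report = mpfa.failure_consistency(fit, {"hi": 0.01}, {"hi": 75})
        assert report[0]["flagged"]
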