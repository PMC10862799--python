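import math
import warnings

import numpy as np
import pytest

from npbddm.bounds import BoundCurve
from npbddm.ddm_sim import DDMParams, simulate_decision_times
from npbddm.fokker_planck import first_passage_densities
from npbddm.npb_ddm import (
    DecisionTimeDensity, NonparametricBoundDDM, derive_bounds,
    epanechnikov_kernel, estimate_decision_time_density, log_likelihood,
    predict_joint, _extract_trials,
)
from npbddm.trial_data import COHERENCES, COHERENCE_WEIGHTS

PRIORS = np.asarray(COHERENCE_WEIGHTS)


def exact_density(theta, bounds, dt=0.0025, dx=0.01):
    """Model decision-time density from the forward propagation (oracle input)."""
    drifts = theta.kappa * np.asarray(COHERENCES)
    _, eu, el = first_passage_densities(drifts, bounds, dx=dx, dt=dt,
                                        t_max=5.0)
    f = PRIORS @ (eu + el)
    n = int(round(5.0 / dt))
    out = np.zeros(n)
    out[:f.size] = f / dt
    out /= out.sum() * dt
    return DecisionTimeDensity(dt=dt, density=out, n_trials=0)


class TestKernelDensity:
    def test_kernel_integrates_to_one_and_is_nonnegative(self):
        h = 0.2236
        u = np.linspace(-0.3, 0.3, 4001)
        k = epanechnikov_kernel(u, h)
        assert (k >= 0).all()
        assert np.trapezoid(k, u) == pytest.approx(1.0, abs=1e-4)

    def test_single_atom_density_is_the_kernel(self):
        r = 0.8
        d = estimate_decision_time_density([r] * 10, mu_nd=0.0, dt=0.001)
        h = 0.1 * math.sqrt(5)
        expected = epanechnikov_kernel(d.times - r, h)
        expected /= expected.sum() * 0.001  # grid renormalization
        np.testing.assert_allclose(d.density, expected, atol=1e-9)

    def test_matches_bruteforce_kde(self, rng):
        rts = rng.uniform(0.4, 1.5, size=200)
        mu_nd = 0.25
        d = estimate_decision_time_density(rts, mu_nd, dt=0.002)
        h = 0.1 * math.sqrt(5)
        td = rts - mu_nd
        brute = np.array([
            epanechnikov_kernel(t - td, h).mean() for t in d.times
        ])
        brute /= brute.sum() * d.dt
        np.testing.assert_allclose(d.density, brute, atol=1e-12)

    def test_truncation_renormalizes(self, rng):
        rts = rng.uniform(0.3, 0.6, size=500)
        d = estimate_decision_time_density(rts, mu_nd=0.35, dt=0.001)
        assert d.integral() == pytest.approx(1.0, abs=1e-3)

    def test_empty_and_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            estimate_decision_time_density([], 0.1)
        with pytest.raises(ValueError):
            estimate_decision_time_density([0.1, 0.2], mu_nd=2.0)


class TestDeriveBounds:
    def test_flat_bound_exact_density_round_trip(self, theta):
        b0 = 1.0
        flat = BoundCurve.flat(b0, 5.0, dt=0.0025)
        dens = exact_density(theta, flat)
        got = derive_bounds(dens, theta, PRIORS, dx=0.01, x_max=2.0)
        cdf = np.cumsum(dens.density) * dens.dt
        q5 = dens.times[np.searchsorted(cdf, 0.05)]
        q95 = dens.times[np.searchsorted(cdf, 0.95)]
        tt = np.arange(q5, q95, 0.01)
        assert np.max(np.abs(got(tt) - b0)) < 0.05 * b0

    def test_collapse_slope_recovered_from_exact_density(self, theta):
        true = BoundCurve.linear_collapse(1.0, 0.2, 5.0, dt=0.0025)
        dens = exact_density(theta, true)
        got = derive_bounds(dens, theta, PRIORS, dx=0.01, x_max=2.0)
        cdf = np.cumsum(dens.density) * dens.dt
        q10 = dens.times[np.searchsorted(cdf, 0.10)]
        q90 = dens.times[np.searchsorted(cdf, 0.90)]
        slope = np.polyfit([q10, q90], [got(q10), got(q90)], 1)[0]
        assert abs(-slope - 0.2) < 0.1 * 0.2

    def test_zero_early_demand_keeps_bound_at_ceiling(self, theta):
        dens_vals = np.zeros(400)
        dens_vals[200:] = 1.0
        dens_vals /= dens_vals.sum() * 0.0025
        dens = DecisionTimeDensity(dt=0.0025, density=dens_vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # late demand eventually clamps
            got = derive_bounds(dens, theta, PRIORS, dx=0.02, x_max=2.0)
        assert got(0.1) == pytest.approx(2.0, abs=0.02)

    def test_excess_demand_clamps_bound_to_zero_with_warning(self, theta):
        # late uniform demand outruns the interior mass that can still exit
        dens_vals = np.zeros(400)
        dens_vals[200:] = 1.0
        dens_vals /= dens_vals.sum() * 0.0025
        dens = DecisionTimeDensity(dt=0.0025, density=dens_vals)
        with pytest.warns(UserWarning, match="clamped"):
            got = derive_bounds(dens, theta, PRIORS, dx=0.02, x_max=2.0)
        assert got.values[-1] == 0.0


class TestPredictJoint:
    def test_sigma_zero_is_pure_shift(self, theta):
        bounds = BoundCurve.linear_collapse(1.0, 0.3, 3.0, dt=0.0025)
        th0 = DDMParams(theta.kappa, 0.3, 0.0)
        jp = predict_joint(th0, bounds, dx=0.02, t_max=3.0)
        drifts = th0.kappa * np.asarray(COHERENCES)
        times, eu, _ = first_passage_densities(drifts, bounds, dx=0.02,
                                               t_max=3.0)
        i = list(COHERENCES).index(0.512)
        shift = int(round(0.3 / 0.0025))
        fp_peak = times[np.argmax(eu[i])] + 0.3
        rt_peak = jp.times[np.argmax(jp.upper[i])]
        assert abs(fp_peak - rt_peak) <= 0.0025 + 1e-9

    def test_choice_and_rt_densities_normalize(self, theta):
        bounds = BoundCurve.linear_collapse(1.0, 0.3, 3.0, dt=0.0025)
        jp = predict_joint(theta, bounds, dx=0.02, t_max=3.0)
        for coh in COHERENCES:
            total = (jp.choice_probability(coh, "right")
                     + jp.choice_probability(coh, "left"))
            assert total == pytest.approx(1.0, abs=1e-3)

    def test_choice_probability_matches_simulation(self, theta, rng):
        bounds = BoundCurve.linear_collapse(1.0, 0.3, 3.0, dt=0.0025)
        jp = predict_joint(theta, bounds, dx=0.01, t_max=3.0)
        n = 20000
        sign, _ = simulate_decision_times(
            np.full(n, theta.kappa * 0.512), bounds, rng, dt=0.001, t_max=3.0)
        p_sim = (sign > 0).mean()
        p_mod = jp.choice_probability(0.512, "right")
        assert abs(p_sim - p_mod) < 3 * math.sqrt(p_mod * (1 - p_mod) / n)


class TestLikelihoodAndEstimator:
    def test_loglik_scales_with_duplication(self, theta, standard_trials):
        cohs, choices, rts = _extract_trials(standard_trials)
        bounds = BoundCurve.linear_collapse(1.0, 0.15, 5.0, dt=0.005)
        jp = predict_joint(theta, bounds, dx=0.02)
        ll1 = log_likelihood(jp, cohs, choices, rts)
        ll2 = log_likelihood(jp, np.tile(cohs, 2), np.tile(choices, 2),
                             np.tile(rts, 2))
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_fit_requires_completed_trials(self, standard_trials):
        from npbddm.trial_data import TrialRecord

        aborted = TrialRecord("A", "I", 1, 999, 0.0, "left", False, None,
                              None, None, "aborted", 0)
        est = NonparametricBoundDDM()
        with pytest.raises(ValueError, match="completed"):
            est.fit(list(standard_trials[:20]) + [aborted])

    def test_estimator_round_trip_smoke(self, theta, standard_trials):
        """Tiny-budget fit: runs end to end and lands near the generator."""
        est = NonparametricBoundDDM(dt=0.0075, dx=0.025, x_max=2.0,
                                    n_restarts=0, max_iter=25,
                                    kappa0=14.0, mu_nd0=0.25,
                                    random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(standard_trials)
        assert 10.0 < est.kappa_ < 25.0
        assert 0.15 < est.mu_nd_ < 0.40
        assert est.bounds_.values.min() >= 0.0
        assert est.score(standard_trials) == pytest.approx(
            est.log_likelihood_ / est.n_trials_, rel=1e-9)
        # sklearn-style parameter handling
        assert est.get_params()["dx"] == 0.025

    def test_monotone_time_dependent_accuracy_under_collapse(
            self, theta, standard_trials):
        """Faster decisions are more accurate at mid coherence (collapse)."""
        recs = [r for r in standard_trials if abs(r.coherence) == 0.128]
        recs.sort(key=lambda r: r.rt_s)
        half = len(recs) // 2
        acc_fast = np.mean([r.outcome == "correct" for r in recs[:half]])
        acc_slow = np.mean([r.outcome == "correct" for r in recs[half:]])
        assert acc_fast > acc_slow
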