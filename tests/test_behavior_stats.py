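import numpy as np
import pandas as pd
import pytest

from npbddm.behavior_stats import (
    accuracy_phase_logistic, cancellation_aligned_rt,
    pre_post_cancellation_test, rt_phase_regression, time_dependent_accuracy,
)
from npbddm.trial_data import MOTION_STRENGTHS, TrialRecord


def synth_records(rng, n, phase, rt_shift=0.0, acc_boost=0.0,
                  participant="A", session=1):
    """Analytically controlled trials: RT = base(strength) + noise,
    accuracy = sigmoid-like in strength."""
    recs = []
    strengths = np.asarray(MOTION_STRENGTHS)
    for i in range(n):
        s = float(rng.choice(strengths))
        rt = max(0.15, 1.0 - 1.2 * s + rng.normal(0, 0.15) + rt_shift)
        p = 1.0 / (1.0 + np.exp(-(8.0 * s + acc_boost)))
        correct = rng.random() < p
        side = "right" if rng.random() < 0.5 else "left"
        choice = side if correct else ("left" if side == "right" else "right")
        recs.append(TrialRecord(participant, phase, session, i + 1,
                                s if side == "right" else -s, side, False,
                                None, choice, min(rt, 5.0),
                                "correct" if correct else "error",
                                1 if correct else -1))
    return recs


class TestRtRegression:
    def test_known_shift_recovered(self, rng):
        p1 = synth_records(rng, 3000, "I")
        p2 = synth_records(rng, 3000, "II", rt_shift=-0.1)
        res = rt_phase_regression(p1 + p2)
        assert res.beta_phase == pytest.approx(-0.1, abs=0.02)
        assert res.pvalue < 1e-6

    def test_null_has_small_phase_coefficient(self, rng):
        p1 = synth_records(rng, 2000, "I")
        p2 = synth_records(rng, 2000, "II")
        res = rt_phase_regression(p1 + p2)
        assert abs(res.statistic) < 4.0

    def test_matches_closed_form_ols(self, rng):
        p1 = synth_records(rng, 400, "I")
        p2 = synth_records(rng, 400, "II", rt_shift=-0.05)
        res = rt_phase_regression(p1 + p2)
        # normal-equations oracle
        df = pd.DataFrame([{
            "rt": r.rt_s, "s": abs(r.coherence), "ph": r.phase == "II"}
            for r in p1 + p2 if r.outcome == "correct"])
        strengths = np.sort(df["s"].unique())
        X = np.column_stack([(df["s"] == s).astype(float) for s in strengths]
                            + [df["ph"].astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ df["rt"].to_numpy())
        assert res.beta_phase == pytest.approx(beta[-1], abs=1e-8)

    def test_missing_phase_is_an_error(self, rng):
        with pytest.raises(ValueError):
            rt_phase_regression(synth_records(rng, 100, "I"),
                                phases=("I", "II"))


class TestAccuracyLogistic:
    def test_lower_accuracy_phase_negative_coefficient(self, rng):
        p1 = synth_records(rng, 3000, "I")
        p2 = synth_records(rng, 3000, "II", acc_boost=-0.4)
        res = accuracy_phase_logistic(p1 + p2)
        assert res.beta_phase < 0
        assert res.pvalue < 0.01

    def test_matches_handrolled_irls(self, rng):
        p1 = synth_records(rng, 800, "I")
        p2 = synth_records(rng, 800, "II", acc_boost=-0.3)
        res = accuracy_phase_logistic(p1 + p2)
        recs = [r for r in p1 + p2 if r.completed]
        y = np.array([r.outcome == "correct" for r in recs], dtype=float)
        X = np.column_stack([
            [abs(r.coherence) for r in recs],
            [1.0 if r.phase == "II" else 0.0 for r in recs],
        ])
        beta = np.zeros(2)
        for _ in range(50):  # plain Newton / IRLS oracle
            eta = X @ beta
            mu = 1 / (1 + np.exp(-eta))
            w = mu * (1 - mu)
            step = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (y - mu))
            beta += step
            if np.abs(step).max() < 1e-12:
                break
        assert res.beta_phase == pytest.approx(beta[1], abs=1e-6)
        assert res.params["strength"] == pytest.approx(beta[0], abs=1e-6)

    def test_pooled_model_has_per_participant_slopes(self, rng):
        recs = []
        for subj in "AB":
            recs += synth_records(rng, 500, "I", participant=subj)
            recs += synth_records(rng, 500, "II", participant=subj)
        res = accuracy_phase_logistic(recs, pooled=True)
        assert {"strength_A", "strength_B", "phase"} <= set(res.params.index)

    def test_chance_level_pinned_at_zero_strength(self, rng):
        """No intercept: predicted accuracy at 0% coherence in the
        reference phase is exactly one half."""
        p1 = synth_records(rng, 800, "I")
        p2 = synth_records(rng, 800, "II")
        res = accuracy_phase_logistic(p1 + p2)
        eta0 = res.params["strength"] * 0.0  # phase-I row at zero strength
        assert 1 / (1 + np.exp(-eta0)) == 0.5


class TestTimeDependentAccuracy:
    def test_all_correct_flat_at_one(self, rng):
        recs = [r for r in synth_records(rng, 300, "I")
                if r.outcome == "correct"]
        curves = time_dependent_accuracy(recs, window_trials=50)
        for frame in curves.values():
            np.testing.assert_allclose(frame["accuracy"], 1.0, atol=1e-12)

    def test_window_equal_to_n_gives_overall_accuracy(self, rng):
        recs = synth_records(rng, 80, "I")
        sub = [r for r in recs if abs(r.coherence) == 0.128]
        curves = time_dependent_accuracy(sub, window_trials=10 ** 6)
        frame = curves[0.128]
        overall = np.mean([r.outcome == "correct" for r in sub])
        assert len(frame) == 1
        assert frame["accuracy"].iloc[0] == pytest.approx(overall)
        assert frame.attrs["single_window"]

    def test_declines_with_rt_under_collapsing_bounds(self, standard_trials):
        curves = time_dependent_accuracy(standard_trials, window_trials=80)
        frame = curves[0.128]
        n = len(frame)
        assert frame["accuracy"].iloc[: n // 3].mean() \
            > frame["accuracy"].iloc[-n // 3:].mean()


def cancellation_fixture(rng, n_sessions=8, n=120, effect=0.0):
    """Sessions with one mid-session cancellation; trials after it get an
    ``effect`` shift (in z units of the RT noise scale)."""
    recs = []
    for sess in range(1, n_sessions + 1):
        cancel_at = 40 + int(rng.integers(0, 40))
        for i in range(n):
            s = float(rng.choice(MOTION_STRENGTHS))
            if i == cancel_at:
                recs.append(TrialRecord("A", "II", sess, i + 1, s, "right",
                                        True, 1.0, None, None, "canceled", 0))
                continue
            shift = effect if 0 < i - cancel_at <= 5 else 0.0
            rt = max(0.1, 0.8 - 0.5 * s + rng.normal(0, 0.2) + shift)
            recs.append(TrialRecord("A", "II", sess, i + 1, s, "right", False,
                                    None, "right", min(rt, 5.0), "correct", 1))
    return recs


class TestCancellationAlignment:
    def test_null_generator_lag_means_near_zero(self, rng):
        recs = cancellation_fixture(rng, n_sessions=40, effect=0.0)
        aligned = cancellation_aligned_rt(recs)
        # 40 events per lag: |mean z| should stay within ~3/sqrt(40)
        assert np.nanmax(np.abs(aligned["mean_z"])) < 0.5

    def test_constructed_speedup_after_cancellation(self, rng):
        recs = cancellation_fixture(rng, effect=-0.3)
        aligned = cancellation_aligned_rt(recs)
        post = aligned.loc[[1, 2, 3], "mean_z"].mean()
        pre = aligned.loc[[-3, -2, -1], "mean_z"].mean()
        assert post < pre - 0.5
        stat, p = pre_post_cancellation_test(recs)
        assert p < 0.01 and stat > 0

    def test_single_cancellation_at_session_start(self):
        recs = [TrialRecord("A", "II", 1, 1, 0.128, "right", True, 0.9,
                            None, None, "canceled", 0)]
        for i in range(2, 8):
            recs.append(TrialRecord("A", "II", 1, i, 0.128, "right", False,
                                    None, "right", 0.6 + 0.01 * i, "correct", 1))
        aligned = cancellation_aligned_rt(recs)
        assert aligned.loc[-1, "n"] == 0
        assert aligned.loc[1, "n"] == 1

    def test_no_cancellations_warns_and_returns_empty(self, rng):
        recs = synth_records(rng, 50, "II")
        with pytest.warns(UserWarning, match="no canceled"):
            out = cancellation_aligned_rt(recs)
        assert out.empty

    def test_zscores_standardize_within_strength(self, rng):
        recs = synth_records(rng, 2000, "II")
        df = pd.DataFrame([{"s": abs(r.coherence), "rt": r.rt_s}
                           for r in recs if r.completed])
        for s, grp in df.groupby("s"):
            z = (grp["rt"] - grp["rt"].mean()) / grp["rt"].std(ddof=0)
            assert abs(z.mean()) < 1e-12
            assert z.std(ddof=0) == pytest.approx(1.0)
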