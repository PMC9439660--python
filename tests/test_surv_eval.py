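"""KM, log-rank, Cox, concordance, td-ROC, calibration, and NRI contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from histoscore import surv_eval as se


class TestKaplanMeier:
    def test_all_censored_survival_stays_at_one(self):
        km = se.km_curve(np.array([1.0, 2.0, 3.0]), np.zeros(3, int))
        assert np.all(km.survival == 1.0)

    def test_hand_product_limit(self):
        km = se.km_curve(np.array([1.0, 2.0, 3.0]), np.ones(3, int))
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.0) == pytest.approx(1 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_censoring_after_last_event_adds_no_drop(self):
        km = se.km_curve(np.array([1.0, 2.0, 3.0, 9.0]), np.array([1, 1, 1, 0]))
        assert km.survival_at(9.0) == pytest.approx(km.survival_at(3.0))
        # and censoring *within* follow-up only rescales risk sets:
        # S after the last event equals the product-limit by hand
        assert km.survival_at(3.0) == pytest.approx((3 / 4) * (2 / 3) * (1 / 2))

    def test_full_event_data_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(1, 10, 50)
        km = se.km_curve(t, np.ones(50, int))
        for q in (2.0, 5.0, 8.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 100)
        e = rng.binomial(1, 0.6, 100)
        km = se.km_curve(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert km.survival_at(0.0) == 1.0

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            se.km_curve(np.array([-1.0, 2.0]), np.array([1, 1]))


def _hand_logrank(time, event, group):
    """Transparent O−E/V computation over distinct event times."""
    o_minus_e, v = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v


class TestLogrank:
    def test_identical_duplicated_groups_give_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array(["a"] * 3 + ["b"] * 3)
        stat, p = se.logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_eight_subject_hand_oracle(self):
        time = np.array([2.0, 3.0, 5.0, 7.0, 1.0, 4.0, 6.0, 8.0])
        event = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        group = np.array([True] * 4 + [False] * 4)
        stat, _ = se.logrank_test(time, event, np.where(group, "x", "y"))
        assert stat == pytest.approx(_hand_logrank(time, event, group), abs=1e-6)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 40)
        e = rng.binomial(1, 0.7, 40)
        g = rng.choice(["a", "b"], 40)
        s1, p1 = se.logrank_test(t, e, g)
        s2, p2 = se.logrank_test(t, e, np.where(g == "a", "b", "a"))
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            se.logrank_test(np.array([1.0, 2.0]), np.array([1, 1]), np.array(["a", "a"]))


class TestCoxFit:
    def test_binary_covariate_matches_newton_oracle(self):
        """n=20 single binary covariate vs 1-D partial-likelihood search."""
        rng = np.random.default_rng(3)
        x = rng.binomial(1, 0.5, 20).astype(float)
        t = rng.exponential(np.exp(-0.8 * x))
        e = np.ones(20, int)
        res = se.cox_fit(t, e, pd.DataFrame({"x": x}))
        beta_hat = np.log(res.table.loc["x", "HR"])

        from histoscore.risk_model import breslow_loglik

        opt = minimize_scalar(
            lambda b: -breslow_loglik(b * x, t, e), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert beta_hat == pytest.approx(opt.x, abs=1e-5)

    def test_duplicating_subjects_preserves_hr(self):
        """Duplication shifts the Breslow partial likelihood by a constant,
        so the maximizer is invariant; Efron's tie correction (every event
        time becomes a tie pair) perturbs the estimate only slightly."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        t = rng.exponential(np.exp(-0.5 * x))
        e = rng.binomial(1, 0.8, 30)
        from histoscore.risk_model import breslow_loglik

        for beta in (-0.5, 0.2, 0.9):  # exact affine identity under Breslow
            single = breslow_loglik(beta * x, t, e)
            double = breslow_loglik(beta * np.r_[x, x], np.r_[t, t], np.r_[e, e])
            assert double == pytest.approx(2 * single - 2 * e.sum() * np.log(2), rel=1e-12)
        one = se.cox_fit(t, e, pd.DataFrame({"x": x}))
        two = se.cox_fit(np.r_[t, t], np.r_[e, e], pd.DataFrame({"x": np.r_[x, x]}))
        assert two.table.loc["x", "HR"] == pytest.approx(one.table.loc["x", "HR"], rel=0.02)
        width_one = one.table.loc["x", "ci_upper"] - one.table.loc["x", "ci_lower"]
        width_two = two.table.loc["x", "ci_upper"] - two.table.loc["x", "ci_lower"]
        assert width_two < width_one

    def test_null_covariate_ci_coverage(self):
        """~95% of Wald CIs cover HR = 1 for an unrelated covariate."""
        rng = np.random.default_rng(5)
        covered = 0
        reps = 200
        for _ in range(reps):
            n = 500
            x = rng.normal(size=n)
            t = rng.exponential(1, n)
            e = rng.binomial(1, 0.8, n)
            res = se.cox_fit(t, e, pd.DataFrame({"x": x}))
            covered += res.table.loc["x", "ci_lower"] <= 1 <= res.table.loc["x", "ci_upper"]
        assert 0.91 <= covered / reps <= 0.99

    def test_uni_mode_collects_per_covariate_rows(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=100), "b": rng.binomial(1, 0.4, 100)})
        t = rng.exponential(np.exp(-0.5 * X["a"]))
        e = np.ones(100, int)
        res = se.cox_fit(t, e, X, mode="uni")
        assert list(res.table.index) == ["a", "b"]
        assert (res.table["HR"] > 0).all()
        assert ((res.table["ci_lower"] <= res.table["HR"])
                & (res.table["HR"] <= res.table["ci_upper"])).all()

    def test_too_few_events_rejected(self):
        X = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        with pytest.raises(ValueError, match="events"):
            se.cox_fit(np.arange(1.0, 6.0), np.array([1, 0, 0, 0, 0]), X)


class TestHarrellC:
    def test_orientation_convention(self):
        """Score = time rank (anti-risk) gives C = 0; negated gives 1."""
        rng = np.random.default_rng(7)
        t = rng.uniform(1, 10, 50)
        rank = np.argsort(np.argsort(t)).astype(float)
        c0, _ = se.harrell_c(t, np.ones(50, int), rank, ci=False)
        c1, _ = se.harrell_c(t, np.ones(50, int), -rank, ci=False)
        assert c0 == 0.0 and c1 == 1.0

    def test_random_score_near_half(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(5, 1000)
        e = rng.binomial(1, 0.7, 1000)
        c, _ = se.harrell_c(t, e, rng.normal(size=1000), ci=False)
        assert abs(c - 0.5) <= 0.03

    def test_six_subject_exhaustive_pair_oracle(self):
        t = np.array([2.0, 5.0, 1.0, 8.0, 4.0, 9.0])
        e = np.array([1, 0, 1, 1, 1, 0])
        s = np.array([3.0, 1.0, 4.0, 1.0, 2.0, 0.5])
        conc, comp = 0.0, 0
        for i in range(6):
            for j in range(6):
                if i == j or not (e[i] == 1 and t[i] < t[j]):
                    continue
                comp += 1
                if s[i] > s[j]:
                    conc += 1
                elif s[i] == s[j]:
                    conc += 0.5
        c, _ = se.harrell_c(t, e, s, ci=False)
        assert c == pytest.approx(conc / comp)

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(5, 80)
        e = rng.binomial(1, 0.7, 80)
        s = rng.normal(size=80)
        a, _ = se.harrell_c(t, e, s, ci=False)
        b, _ = se.harrell_c(t, e, -s, ci=False)
        assert a + b == pytest.approx(1.0)

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(5, 120)
        e = rng.binomial(1, 0.7, 120)
        s = -np.log(t) + rng.normal(0, 0.5, 120)
        c, (lo, hi) = se.harrell_c(t, e, s, n_bootstrap=200, seed=1)
        assert lo <= c <= hi and 0 <= lo and hi <= 1

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            se.harrell_c(np.array([1.0, 2.0]), np.zeros(2, int), np.array([1.0, 2.0]))


class TestTdRocAuc:
    def test_perfect_separation(self):
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, int)
        s = np.array([6.0, 5.0, 4.0, 1.0, 2.0, 3.0])
        assert se.td_roc_auc(t, e, s, horizon=5.0) == pytest.approx(1.0)

    def test_no_censoring_reduces_to_plain_roc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        t = rng.exponential(5, 400)
        e = np.ones(400, int)
        s = -t + rng.normal(0, 2, 400)
        h = 4.0
        assert se.td_roc_auc(t, e, s, h) == pytest.approx(
            roc_auc_score((t <= h).astype(int), s), abs=1e-9
        )

    def test_random_score_near_half(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(5, 800)
        e = rng.binomial(1, 0.7, 800)
        s = rng.normal(size=800)
        assert abs(se.td_roc_auc(t, e, s, 4.0) - 0.5) <= 0.04

    def test_agrees_with_harrell_for_weak_exponential_effect(self):
        """Global C and the horizon AUC estimate the same concordance in
        the weak-effect limit (they diverge as the effect grows, since C
        averages the AUC over all horizons)."""
        rng = np.random.default_rng(13)
        n = 2000
        score = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.3 * score))
        e = np.ones(n, int)
        c, _ = se.harrell_c(t, e, score, ci=False)
        auc = se.td_roc_auc(t, e, score, float(np.median(t)))
        assert abs(c - auc) <= 0.03

    def test_no_cases_or_controls_rejected(self):
        t = np.array([10.0, 11.0, 12.0])
        with pytest.raises(ValueError, match="events"):
            se.td_roc_auc(t, np.ones(3, int), np.arange(3.0), horizon=1.0)
        with pytest.raises(ValueError, match="past"):
            se.td_roc_auc(t, np.ones(3, int), np.arange(3.0), horizon=20.0)


class TestCalibration:
    def test_true_model_predictions_well_calibrated(self):
        """Predictions from the generating model: |pred − obs| ≤ 0.07."""
        rng = np.random.default_rng(14)
        n = 1000
        lp = rng.normal(0, 0.8, n)
        rate = np.exp(lp) / 5.0
        t = rng.exponential(1 / rate)
        e = np.ones(n, int)
        h = 3.0
        pred = 1 - np.exp(-h * rate)
        cal = se.calibration_curve(pred, t, e, horizon=h)
        assert len(cal) == 4
        assert (np.abs(cal["mean_predicted"] - cal["observed"]) <= 0.07).all()

    def test_constant_prediction_single_bin_matches_marginal(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(5, 300)
        e = np.ones(300, int)
        h = 3.0
        marginal = 1 - se.km_curve(t, e).survival_at(h)
        with pytest.warns(UserWarning):
            cal = se.calibration_curve(np.full(300, marginal), t, e, horizon=h)
        assert len(cal) == 1
        assert cal["observed"].iloc[0] == pytest.approx(marginal)

    def test_monotone_bins_for_monotone_model(self):
        rng = np.random.default_rng(16)
        n = 1200
        lp = rng.normal(0, 1.0, n)
        rate = np.exp(lp) / 5.0
        t = rng.exponential(1 / rate)
        pred = 1 - np.exp(-3.0 * rate)
        cal = se.calibration_curve(pred, t, np.ones(n, int), horizon=3.0)
        assert (np.diff(cal["observed"]) > -0.02).all()

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(ValueError):
            se.calibration_curve(np.array([0.5, 1.5]), np.array([1.0, 2.0]),
                                 np.array([1, 1]), horizon=1.0)


class TestNri:
    def test_identical_scores_give_zero(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(5, 50)
        e = rng.binomial(1, 0.8, 50)
        s = rng.normal(size=50)
        v, ci = se.nri(s, s.copy(), t, e, horizon=2.0, n_bootstrap=50, seed=0)
        assert v == 0.0
        assert ci == (0.0, 0.0)

    def test_informative_score_beats_noise(self):
        """True predictor vs noise: NRI > 0 with CI excluding 0 (n = 600)."""
        rng = np.random.default_rng(18)
        n = 600
        lp = rng.normal(0, 1.5, n)
        t = rng.exponential(np.exp(-lp) * 5)
        c = rng.uniform(0, 30, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        noise = rng.normal(size=n)
        v, (lo, hi) = se.nri(lp, noise, time, event, horizon=3.0,
                             n_bootstrap=300, seed=1)
        assert v > 0 and lo > 0

    def test_ten_subject_hand_oracle_no_censoring(self):
        t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        e = np.ones(10, int)
        new = np.array([5, 4, 6, 1, 2, 3, 0, 1, 2, 0], float)
        old = np.array([4, 5, 5, 2, 1, 3.5, 1, 0, 2, 1], float)
        h = 4.5
        is_event = t <= h
        up = new > old
        down = new < old
        expected = (
            (up[is_event].mean() - down[is_event].mean())
            + (down[~is_event].mean() - up[~is_event].mean())
        )
        v, _ = se.nri(new, old, t, e, horizon=h, ci=False)
        assert v == pytest.approx(expected, abs=1e-12)

    def test_horizon_beyond_followup_rejected(self):
        with pytest.raises(ValueError, match="follow-up"):
            se.nri(np.arange(3.0), np.arange(3.0), np.array([1.0, 2, 3]),
                   np.ones(3, int), horizon=10.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same subjects"):
            se.nri(np.arange(3.0), np.arange(4.0), np.array([1.0, 2, 3]),
                   np.ones(3, int), horizon=1.0)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=30)
@given(
    st.lists(
        st.tuples(st.floats(0.01, 100.0), st.booleans()),
        min_size=2, max_size=40,
    )
)
def test_km_curve_is_a_valid_survival_function(subjects):
    """S(0) = 1, S non-increasing, S ∈ [0, 1], for arbitrary data."""
    time = np.array([t for t, _ in subjects])
    event = np.array([int(e) for _, e in subjects])
    km = se.km_curve(time, event)
    assert km.survival_at(0.0) == 1.0
    assert np.all((km.survival >= -1e-12) & (km.survival <= 1 + 1e-12))
    assert np.all(np.diff(km.survival) <= 1e-12)
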