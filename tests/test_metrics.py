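"""Survival metrics against independently coded brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from mmsurv.metrics import (
    bootstrap_ci,
    breslow_survival_probability,
    concordance_index,
    cox_hazard_ratio,
    decision_curve,
    ipcw_brier,
    kaplan_meier,
    logrank_test,
    stratify_by_quantile,
    time_dependent_auc,
)


# ---------------------------------------------------------------------------
# oracles, written independently of the implementations they check
# ---------------------------------------------------------------------------


def brute_force_c_index(risks, times, events):
    num = den = 0.0
    n = len(risks)
    for i in range(n):
        for j in range(n):
            if events[i] == 1 and times[i] < times[j]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def rank_sum_auc(scores, labels):
    pos, neg = scores[labels == 1], scores[labels == 0]
    num = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return num / (len(pos) * len(neg))


def brute_force_logrank(ta, ea, tb, eb):
    """Literal observed-minus-expected tabulation over pooled event times."""
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    O = E = V = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & (grp == 1)).sum()
        d = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & (grp == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def random_censored_fixture(rng, n):
    risks = rng.standard_normal(n)
    times = rng.exponential(20, size=n) + 0.01
    events = (rng.random(n) < 0.6).astype(int)
    return risks, times, events


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


class TestConcordance:
    def test_perfect_ranking(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(-t, t, np.ones(4)) == 1.0

    def test_constant_risks_give_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(np.zeros(4), t, np.ones(4)) == 0.5

    def test_pair_enumeration_example(self):
        c = concordance_index(
            np.array([3.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0])
        )
        assert np.isclose(c, 2 / 3)

    def test_matches_brute_force_on_100_fixtures(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            r, t, e = random_censored_fixture(rng, n)
            e[np.argmin(t)] = 1  # guarantee a comparable pair
            r = np.round(r, 1)  # induce risk ties
            assert np.isclose(
                concordance_index(r, t, e), brute_force_c_index(r, t, e), atol=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        r, t, e = random_censored_fixture(rng, 40)
        e[0] = 1
        assert np.isclose(
            concordance_index(r, t, e), concordance_index(np.exp(r) + 5, t, e)
        )

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.zeros(2))


# ---------------------------------------------------------------------------
# time-dependent AUC
# ---------------------------------------------------------------------------


class TestTimeDependentAUC:
    def test_perfect_separation_no_censoring(self):
        t = np.linspace(1, 40, 20)
        auc = time_dependent_auc(-t, t, np.ones(20), horizon=15.0)
        assert np.isclose(auc, 1.0)

    def test_reduces_to_rank_sum_auc_without_censoring(self, rng):
        t = rng.exponential(20, size=60) + 0.1
        r = rng.standard_normal(60)
        h = float(np.median(t))
        label = (t <= h).astype(int)
        auc = time_dependent_auc(r, t, np.ones(60, dtype=int), horizon=h)
        assert np.isclose(auc, rank_sum_auc(r, label), atol=1e-10)

    def test_null_risks_near_half(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(30, size=3000) + 0.1
        e = (rng.random(3000) < 0.7).astype(int)
        r = rng.standard_normal(3000)  # independent of outcome
        auc = time_dependent_auc(r, t, e, horizon=float(np.median(t)))
        assert abs(auc - 0.5) < 0.05

    def test_horizon_beyond_follow_up_rejected(self, rng):
        r, t, e = random_censored_fixture(rng, 20)
        with pytest.raises(ValueError):
            time_dependent_auc(r, t, e, horizon=t.max() + 1)


# ---------------------------------------------------------------------------
# Brier / calibration
# ---------------------------------------------------------------------------


class TestBrier:
    def test_perfect_predictions_no_censoring(self):
        t = np.array([1.0, 2.0, 10.0, 12.0])
        e = np.ones(4, dtype=int)
        p = np.array([1.0, 1.0, 0.0, 0.0])  # event prob by horizon 5
        assert np.isclose(ipcw_brier(p, t, e, 5.0), 0.0)

    def test_constant_half_gives_quarter(self):
        t = np.array([1.0, 2.0, 10.0, 12.0])
        e = np.ones(4, dtype=int)
        assert np.isclose(ipcw_brier(np.full(4, 0.5), t, e, 5.0), 0.25)

    def test_reduces_to_mse_without_censoring(self, rng):
        t = rng.exponential(20, size=50) + 0.1
        e = np.ones(50, dtype=int)
        p = rng.random(50)
        h = float(np.median(t))
        label = (t <= h).astype(float)
        assert np.isclose(ipcw_brier(p, t, e, h), np.mean((p - label) ** 2), atol=1e-10)

    def test_breslow_probabilities_monotone_in_risk(self, rng):
        r, t, e = random_censored_fixture(rng, 80)
        e[:10] = 1
        s = breslow_survival_probability(r, t, e, np.array([-1.0, 0.0, 1.0]), [10.0])
        assert s[0, 0] >= s[1, 0] >= s[2, 0]
        assert np.all((0 <= s) & (s <= 1))


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / hazard ratio
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        km = kaplan_meier(np.array([1.0, 5.0, 9.0]), np.zeros(3))
        assert km.survival_at(100.0) == 1.0

    def test_product_limit_by_hand(self):
        km = kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        assert np.isclose(km.survival_at(1.0), 2 / 3)
        assert np.isclose(km.survival_at(2.0), 2 / 3)  # censoring leaves it
        assert np.isclose(km.survival_at(3.0), 0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=30) + 0.1
        km = kaplan_meier(t, np.ones(30))
        for q in (0.2, 0.5, 0.9):
            tau = np.quantile(t, q)
            assert np.isclose(km.survival_at(tau), (t > tau).mean(), atol=1e-10)

    def test_non_increasing_from_one(self, rng):
        _, t, e = random_censored_fixture(rng, 50)
        tab = kaplan_meier(t, e).table
        assert tab.survival.iloc[0] <= 1.0 + 1e-12
        assert (np.diff(tab.survival) <= 1e-12).all()


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 3.0, 5.0, 8.0])
        e = np.array([1, 0, 1, 1])
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 < 1e-10 and p > 0.999

    def test_symmetric_under_relabeling(self, rng):
        ta, tb = rng.exponential(10, 25) + 0.1, rng.exponential(20, 30) + 0.1
        ea, eb = np.ones(25, dtype=int), np.ones(30, dtype=int)
        s1 = logrank_test(ta, ea, tb, eb)
        s2 = logrank_test(tb, eb, ta, ea)
        assert np.allclose(s1, s2)

    def test_matches_oe_v_tabulation_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            na, nb = rng.integers(5, 25, size=2)
            ta = rng.exponential(10, na) + 0.1
            tb = rng.exponential(15, nb) + 0.1
            ea = (rng.random(na) < 0.7).astype(int)
            eb = (rng.random(nb) < 0.7).astype(int)
            if ea.sum() + eb.sum() == 0:
                ea[0] = 1
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = brute_force_logrank(ta, ea, tb, eb)
            assert np.isclose(chi2, ref, atol=1e-8)
            assert np.isclose(p, chi2_dist.sf(ref, 1), atol=1e-10)


class TestHazardRatio:
    def test_score_equation_zero_at_fit(self, rng):
        x = (rng.random(80) < 0.5).astype(int)
        t = rng.exponential(10 / np.exp(0.8 * x)) + 0.01
        e = np.ones(80, dtype=int)
        res = cox_hazard_ratio(x, t, e)
        # score at the fitted coefficient (independent tabulation)
        beta = res.log_hr
        score = 0.0
        for i in range(80):
            if e[i]:
                rs = t >= t[i]
                w = np.exp(beta * x[rs])
                score += x[i] - (w * x[rs]).sum() / w.sum()
        assert abs(score) < 1e-8

    def test_relabeling_inverts_hr(self, rng):
        x = (rng.random(60) < 0.4).astype(int)
        t = rng.exponential(10, 60) + 0.1
        e = (rng.random(60) < 0.8).astype(int)
        e[:5] = 1
        r1 = cox_hazard_ratio(x, t, e)
        r2 = cox_hazard_ratio(1 - x, t, e)
        assert np.isclose(r1.hazard_ratio, 1 / r2.hazard_ratio, atol=1e-8)

    def test_null_simulation_hr_near_one(self):
        rng = np.random.default_rng(5)
        x = (rng.random(2000) < 0.5).astype(int)
        t = rng.exponential(10, 2000) + 0.01
        e = np.ones(2000, dtype=int)
        res = cox_hazard_ratio(x, t, e)
        assert res.ci_lower <= 1.0 <= res.ci_upper

    def test_matches_lifelines_coefficient(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        x = (rng.random(100) < 0.5).astype(int)
        t = rng.exponential(10 / np.exp(0.5 * x)) + 0.01  # continuous: no ties
        e = (rng.random(100) < 0.85).astype(int)
        res = cox_hazard_ratio(x, t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "t": t, "e": e}), duration_col="t", event_col="e"
        )
        assert np.isclose(res.log_hr, cph.params_["x"], atol=1e-4)

    def test_monotone_likelihood_flagged(self):
        x = np.array([0, 0, 0, 1, 1, 1])
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.array([1, 1, 1, 0, 0, 0])  # no events in group 1
        res = cox_hazard_ratio(x, t, e)
        assert res.monotone and res.ci_upper == np.inf


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


class TestBootstrap:
    def test_constant_metric_zero_width(self, rng):
        r, t, e = random_censored_fixture(rng, 30)
        lo, hi, cv = bootstrap_ci(lambda *a: 0.7, r, t, e, n_boot=50, seed=1)
        assert lo == hi == 0.7 and cv == 0.0

    def test_deterministic_per_seed(self, rng):
        r, t, e = random_censored_fixture(rng, 40)
        e[0] = 1
        a = bootstrap_ci(concordance_index, r, t, e, n_boot=100, seed=3)
        b = bootstrap_ci(concordance_index, r, t, e, n_boot=100, seed=3)
        assert a == b

    def test_ci_brackets_point_estimate(self, rng):
        r, t, e = random_censored_fixture(rng, 100)
        e[:20] = 1
        r = -t + rng.standard_normal(100)  # informative risk
        lo, hi, cv = bootstrap_ci(concordance_index, r, t, e, n_boot=200, seed=5)
        c = concordance_index(r, t, e)
        assert lo <= c <= hi and cv > 0


# ---------------------------------------------------------------------------
# decision curves
# ---------------------------------------------------------------------------


class TestDecisionCurve:
    def test_treat_none_is_zero(self, rng):
        p = rng.random(40)
        t = rng.exponential(10, 40) + 0.1
        df = decision_curve(p, t, np.ones(40, dtype=int), 5.0, [0.1, 0.3])
        assert (df.treat_none == 0).all()

    def test_treat_all_equals_prevalence_at_zero_threshold_limit(self):
        t = np.array([1.0, 2.0, 20.0, 30.0, 40.0])
        e = np.ones(5, dtype=int)
        df = decision_curve(np.full(5, 0.9), t, e, 10.0, [1e-9])
        prev = 2 / 5
        assert np.isclose(df.treat_all.iloc[0], prev, atol=1e-6)

    def test_reduces_to_classification_net_benefit(self, rng):
        """Without censoring NB(p) = TP/n - FP/n * p/(1-p) from the
        contingency table."""
        n = 60
        t = rng.exponential(15, n) + 0.1
        e = np.ones(n, dtype=int)
        p_hat = rng.random(n)
        h = float(np.median(t))
        label = (t <= h).astype(int)
        for thr in (0.2, 0.5, 0.8):
            pos = p_hat >= thr
            tp = (pos & (label == 1)).sum()
            fp = (pos & (label == 0)).sum()
            expected = tp / n - fp / n * thr / (1 - thr)
            df = decision_curve(p_hat, t, e, h, [thr])
            assert np.isclose(df.net_benefit.iloc[0], expected, atol=1e-10)

    def test_threshold_bounds_rejected(self, rng):
        p = rng.random(10)
        t = rng.exponential(10, 10) + 0.1
        with pytest.raises(ValueError):
            decision_curve(p, t, np.ones(10, dtype=int), 5.0, [1.0])


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


class TestStratification:
    def test_hand_computed_median_cutoff(self):
        strat = stratify_by_quantile([1.0, 2.0, 3.0, 4.0], [2.0, 3.0], "median")
        assert np.isclose(strat.cutoffs[0], 2.5)
        assert strat.group_labels == ["low", "high"]

    def test_median_split_balanced(self, rng):
        r = rng.standard_normal(200)
        strat = stratify_by_quantile(r, r, 0.5)
        counts = np.unique(strat.group_labels, return_counts=True)[1]
        assert abs(counts[0] - counts[1]) <= 1

    def test_tertiles_partition_all_patients(self, rng):
        tr, te = rng.standard_normal(90), rng.standard_normal(50)
        strat = stratify_by_quantile(tr, te, "tertiles")
        assert len(strat.cutoffs) == 2
        assert set(strat.group_labels) <= {"q1", "q2", "q3"}
        assert len(strat.group_labels) == 50

    def test_degenerate_training_risks_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_quantile(np.ones(10), np.ones(3), "median")
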