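"""Survival statistics, Welch fold changes and concordance checks."""

import numpy as np
import pandas as pd
import pytest

from phenosig import (
    cox_fit,
    drug_panel_compare,
    foldchange_concordance,
    km_estimate,
    landmark_roc,
    logrank_test,
    simulate_drug_panel,
    simulate_survival,
    welch_t_test,
)


def logrank_oracle(ta, ea, tb, eb):
    """Event-time-by-event-time O-E tabulation with hypergeometric variance."""
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb]).astype(bool)
    group = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    O_minus_E = 0.0
    V = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (group == 0)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


def welch_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return t, df


def pearson_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


class TestKmEstimate:
    def test_no_censoring_equals_empirical_survivor(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert km.at(1.0) == pytest.approx(2 / 3)
        assert km.at(2.5) == pytest.approx(1 / 3)
        assert km.at(3.0) == pytest.approx(0.0)
        assert km.median == pytest.approx(2.0)

    def test_all_censored_flat_curve(self):
        km = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert km.at(5.0) == 1.0
        assert np.isnan(km.median)

    def test_matches_one_minus_ecdf(self, rng):
        times = rng.exponential(2.0, 50)
        km = km_estimate(times, np.ones(50, bool))
        for q in (0.5, 1.0, 2.0):
            assert km.at(q) == pytest.approx((times > q).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        table = pd.DataFrame({"time": [1, 2, 3, 4.0], "event": [True] * 4})
        chi2, p = logrank_test(table, table.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_matches_hand_tabulation_oracle(self, rng):
        ta, tb = rng.exponential(1.0, 20), rng.exponential(2.0, 20)
        ea = rng.uniform(size=20) < 0.8
        eb = rng.uniform(size=20) < 0.8
        chi2, _ = logrank_test(
            pd.DataFrame({"time": ta, "event": ea}),
            pd.DataFrame({"time": tb, "event": eb}),
        )
        assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-9)

    def test_symmetric_in_group_order(self, rng):
        a = pd.DataFrame({"time": rng.exponential(1, 30), "event": True})
        b = pd.DataFrame({"time": rng.exponential(3, 30), "event": True})
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0], rel=1e-12)

    def test_no_events_undefined(self):
        t = pd.DataFrame({"time": [1.0, 2.0], "event": [False, False]})
        chi2, p = logrank_test(t, t.copy())
        assert np.isnan(chi2) and np.isnan(p)


class TestCoxFit:
    @staticmethod
    def _table(n, hr, censor, seed):
        groups = {
            f"P{i}": ("sensitive" if i < n // 2 else "resistant") for i in range(n)
        }
        table = simulate_survival(groups, hazard_ratio=hr, censor_rate=censor, seed=seed)
        table["resistant"] = (table["group"] == "resistant").astype(float)
        return table

    def test_null_covariate_hr_near_one(self):
        table = self._table(1000, 1.0, 0.2, seed=0)
        res = cox_fit(table, ["resistant"])
        assert 0.8 <= res.loc["resistant", "hazard_ratio"] <= 1.25

    def test_recovers_log_hazard_ratio(self):
        """Two-group HR=2 at n=1000 with 20% censoring: ln HR within 0.15."""
        errs = []
        for seed in range(5):
            table = self._table(1000, 2.0, 0.2, seed=seed)
            res = cox_fit(table, ["resistant"])
            errs.append(np.log(res.loc["resistant", "hazard_ratio"]) - np.log(2))
        assert abs(np.mean(errs)) < 0.15

    def test_bias_shrinks_with_n(self):
        errs = {}
        for n in (200, 1000):
            e = []
            for seed in range(5):
                table = self._table(n, 2.0, 0.2, seed=100 + seed)
                res = cox_fit(table, ["resistant"])
                e.append(abs(np.log(res.loc["resistant", "hazard_ratio"]) - np.log(2)))
            errs[n] = np.mean(e)
        assert errs[1000] < errs[200]

    def test_single_level_covariate_flagged_inestimable(self):
        table = self._table(100, 2.0, 0.1, seed=1)
        table["stage_m"] = "M0"  # one observed level, like a degenerate stage
        res = cox_fit(table, ["resistant", "stage_m"])
        assert res.loc["stage_m", "estimable"] == False  # noqa: E712
        assert np.isnan(res.loc["stage_m", "hazard_ratio"])
        assert res.loc["resistant", "estimable"] == True  # noqa: E712
        assert res.loc["resistant", "ci_low"] <= res.loc["resistant", "hazard_ratio"]
        assert res.loc["resistant", "hazard_ratio"] <= res.loc["resistant", "ci_high"]

    def test_no_events_rejected(self):
        table = pd.DataFrame({"time": [1.0, 2.0], "event": [False, False], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(table, ["x"])


class TestLandmarkRoc:
    def test_scores_equal_event_indicator(self):
        times = np.array([1.0, 1.5, 6.0, 7.0])
        events = np.array([True, True, False, False])
        scores = np.array([1.0, 1.0, 0.0, 0.0])
        assert landmark_roc(scores, times, events, horizon=4.0) == 1.0

    def test_censored_before_horizon_excluded(self):
        times = np.array([1.0, 3.0, 6.0])
        events = np.array([True, False, False])  # patient 2 censored at 3y
        scores = np.array([0.9, 0.5, 0.1])
        # only patients 1 (positive) and 3 (negative) remain
        assert landmark_roc(scores, times, events, horizon=4.0) == 1.0

    def test_random_scores_chance_level(self, rng):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            times = r.exponential(4.0, 100)
            aucs.append(
                landmark_roc(r.uniform(size=100), times, np.ones(100, bool), 3.0)
            )
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_empty_class_undefined(self):
        auc = landmark_roc([0.5, 0.6], [10.0, 12.0], [False, False], horizon=2.0)
        assert np.isnan(auc)


class TestWelch:
    def test_identical_arms(self):
        t, df, p = welch_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        t, df, p = welch_t_test([1.0, 2, 3], [4.0, 5, 6])
        t0, df0 = welch_oracle([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(t0, abs=1e-9)
        assert df == pytest.approx(df0, abs=1e-9)

    def test_agrees_with_pooled_test_under_equal_variance(self, rng):
        from scipy import stats

        x = rng.normal(0, 1, 60)
        y = rng.normal(0.3, 1, 60)
        _, _, p_welch = welch_t_test(x, y)
        p_pooled = stats.ttest_ind(x, y, equal_var=True).pvalue
        assert p_welch == pytest.approx(p_pooled, rel=0.05)

    def test_degenerate_constant_arms(self):
        t, _, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0


class TestDrugPanel:
    @staticmethod
    def _labels(n=80):
        return pd.Series(
            {f"C{i}": ("resistant" if i % 2 else "sensitive") for i in range(n)}
        )

    def test_null_drug_fold_change_near_one(self):
        labels = self._labels()
        panel = simulate_drug_panel(labels.to_dict(), {"null_drug": 0.0}, seed=0)
        results, skipped = drug_panel_compare(panel, labels)
        r = results[0]
        assert r.ci_low <= 1.0 <= r.ci_high
        assert r.p > 0.05

    def test_planted_four_fold_shift(self):
        labels = self._labels()
        panel = simulate_drug_panel(labels.to_dict(), {"shifted": 2.0}, seed=1)
        results, _ = drug_panel_compare(panel, labels)
        assert 3.0 <= results[0].fold_change <= 5.4
        assert results[0].p < 1e-6

    def test_fold_change_inside_its_ci(self, rng):
        labels = self._labels()
        panel = simulate_drug_panel(
            labels.to_dict(), {f"d{i}": e for i, e in enumerate([-1.0, 0.0, 0.5, 2.0])},
            seed=2,
        )
        results, _ = drug_panel_compare(panel, labels, bh_correct=True)
        for r in results:
            assert r.ci_low <= r.fold_change <= r.ci_high
            assert r.padj is not None and r.padj >= r.p - 1e-15

    def test_log_fc_equals_mean_log_difference(self):
        labels = self._labels()
        panel = simulate_drug_panel(labels.to_dict(), {"d": 1.0}, seed=3)
        results, _ = drug_panel_compare(panel, labels)
        logs = np.log(panel["d"])
        expected = logs[labels == "resistant"].mean() - logs[labels == "sensitive"].mean()
        assert np.log(results[0].fold_change) == pytest.approx(expected, abs=1e-12)

    def test_small_arm_skipped_with_reason(self):
        labels = pd.Series({"C0": "sensitive", "C1": "sensitive", "C2": "resistant"})
        panel = pd.DataFrame({"d": [1.0, 2.0, 3.0]}, index=labels.index)
        results, skipped = drug_panel_compare(panel, labels)
        assert results == []
        assert "insufficient arm size" in skipped["d"]


class TestConcordance:
    def test_identical_and_negated_vectors(self):
        r, _ = foldchange_concordance([1.0, 2, 3], [1.0, 2, 3])
        assert r == pytest.approx(1.0)
        r, _ = foldchange_concordance([1.0, 2, 3], [-1.0, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_closed_form_oracle(self):
        r, p = foldchange_concordance([1.0, 2, 3], [2.0, 4, 7])
        assert r == pytest.approx(pearson_oracle([1, 2, 3], [2, 4, 7]), abs=1e-12)

    def test_zero_variance_undefined(self):
        r, p = foldchange_concordance([1.0, 1, 1], [1.0, 2, 3])
        assert np.isnan(r) and np.isnan(p)
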