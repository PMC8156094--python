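"""Screening statistics: confusion metrics, ROC/AUC, Youden sweep, odds
ratios — including the values the screening study prints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tugfall as tf
from tugfall.clinmetrics import ConfusionMatrix, CutoffRule


def brute_force_auc(scores, labels):
    """Independent pair-enumeration oracle for the Mann-Whitney AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        y = np.array([1] * 5 + [0] * 5)
        cm = tf.confusion(y, y)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 0, 0, 5)

    def test_complement(self):
        y = np.array([1, 1, 0, 0])
        cm = tf.confusion(1 - y, y)
        assert cm.tp == cm.tn == 0

    def test_followup_survey_counts(self):
        """87 follow-up respondents, 25 reported falls; 28 false positives
        and 6 false negatives leave tp=19, tn=34."""
        true = np.array([1] * 25 + [0] * 62)
        pred = np.concatenate([
            np.ones(19), np.zeros(6),      # fallers: 19 caught, 6 missed
            np.ones(28), np.zeros(34)])    # non-fallers: 28 false alarms
        cm = tf.confusion(pred, true)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (19, 28, 6, 34)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tf.confusion([], [])


class TestBasicMetrics:
    def test_geriatrician_followup_metrics(self):
        m = tf.basic_metrics(ConfusionMatrix(tp=19, fp=28, fn=6, tn=34))
        assert m["Acc"] == pytest.approx(0.609, abs=5e-4)
        assert m["Se"] == pytest.approx(0.760, abs=5e-4)
        assert m["Sp"] == pytest.approx(0.548, abs=5e-4)
        assert m["F1"] == pytest.approx(0.528, abs=5e-4)

    def test_tug_cutoff_metrics(self):
        """TUG >= 14 s on 54 fallers / 46 non-fallers."""
        m = tf.basic_metrics(ConfusionMatrix(tp=30, fp=5, fn=24, tn=41))
        assert m["Acc"] == pytest.approx(0.7100, abs=1e-4)
        assert m["Se"] == pytest.approx(0.5556, abs=1e-4)
        assert m["Sp"] == pytest.approx(0.8913, abs=1e-4)
        assert m["J"] == pytest.approx(0.4468, abs=1e-4)

    def test_perfect_matrix(self):
        m = tf.basic_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert all(m[k] == 1.0 for k in ("Acc", "Se", "Sp", "F1", "J"))

    def test_zero_denominator_gives_nan(self):
        m = tf.basic_metrics(ConfusionMatrix(tp=0, fp=3, fn=0, tn=7))
        assert np.isnan(m["Se"])
        assert not np.isnan(m["Sp"])

    @settings(deadline=None, max_examples=100)
    @given(st.tuples(*[st.integers(0, 50)] * 4).filter(
        lambda t: sum(t) > 0))
    def test_identities_hold(self, cells):
        cm = ConfusionMatrix(*cells)
        m = tf.basic_metrics(cm)
        assert m["Acc"] * cm.n == pytest.approx(cm.tp + cm.tn)
        if not (np.isnan(m["Se"]) or np.isnan(m["Sp"])):
            assert m["J"] == pytest.approx(m["Se"] + m["Sp"] - 1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert tf.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert tf.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_enumerated_example(self):
        auc = tf.roc_auc([0.9, 0.8, 0.85, 0.1], [1, 1, 0, 0])
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tf.roc_auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, max_examples=60)
    @given(st.integers(1, 100), st.integers(1, 100), st.integers(0, 10 ** 6))
    def test_matches_brute_force(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        # discretized scores force ties
        scores = rng.integers(0, 8, n_pos + n_neg) / 7.0
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        assert tf.roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        assert tf.roc_auc(np.exp(scores), labels) == pytest.approx(
            tf.roc_auc(scores, labels))


class TestCStatistic:
    def test_chance_auc(self):
        res = tf.c_statistic_test([0.2, 0.2, 0.2, 0.2], [1, 1, 0, 0])
        assert res["auc"] == 0.5
        assert res["z"] == 0.0
        assert res["p_one_sided"] == 0.5

    def test_separable_large_n_significant(self, rng):
        scores = np.r_[rng.normal(2, 1, 100), rng.normal(0, 1, 100)]
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        res = tf.c_statistic_test(scores, labels)
        assert res["p_one_sided"] < 0.001
        assert res["ci_low"] <= res["auc"] <= res["ci_high"]

    def test_hanley_se_close_to_bootstrap_se(self):
        """Hanley-McNeil SE within 20% of a bootstrap SE on a 50+50
        sample."""
        rng = np.random.default_rng(7)
        scores = np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)]
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        se = tf.c_statistic_test(scores, labels)["se"]
        boot = []
        for _ in range(400):
            idx = np.r_[rng.choice(50, 50), 50 + rng.choice(50, 50)]
            boot.append(tf.roc_auc(scores[idx], labels[idx]))
        assert se == pytest.approx(np.std(boot, ddof=1), rel=0.20)

    def test_delong_option_agrees_roughly(self, rng):
        scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 40)]
        labels = np.r_[np.ones(40, int), np.zeros(40, int)]
        h = tf.c_statistic_test(scores, labels, method="hanley")
        d = tf.c_statistic_test(scores, labels, method="delong")
        assert h["auc"] == d["auc"]
        assert d["se"] == pytest.approx(h["se"], rel=0.5)

    def test_degenerate_flagged(self):
        res = tf.c_statistic_test([1.0, 0.0], [1, 0])
        assert res["degenerate"]
        assert res["p_one_sided"] == 0.0


class TestDichotomize:
    def test_tug_boundary_inclusive(self):
        rule = CutoffRule("tug_time_s", 14.0, "high_is_faller")
        np.testing.assert_array_equal(
            tf.dichotomize([13.9, 14.0, 20.0], rule), [0, 1, 1])

    def test_chair_stand_boundary(self):
        rule = CutoffRule("chair_stands", 8.0, "low_is_faller")
        np.testing.assert_array_equal(
            tf.dichotomize([8, 9], rule), [1, 0])

    def test_degenerate_cutoff(self):
        rule = CutoffRule("x", -np.inf, "high_is_faller")
        assert tf.dichotomize([0.0, 5.0], rule).all()

    def test_direction_must_be_explicit(self):
        with pytest.raises(ValueError):
            CutoffRule("x", 1.0, "auto")


class TestYouden:
    def test_separable(self):
        res = tf.youden_optimal_cutoff([20, 30, 10, 12], [1, 1, 0, 0])
        assert res["cutoff"] == 20
        assert res["J_max"] == 1.0

    def test_matches_exhaustive_search(self, rng):
        values = rng.normal(size=80)
        labels = (values + rng.normal(0, 1, 80) > 0).astype(int)
        labels[:2] = [0, 1]
        res = tf.youden_optimal_cutoff(values, labels)
        best = max(
            (tf.basic_metrics(tf.confusion(
                (values >= c).astype(int), labels))["J"]
             for c in np.unique(values)))
        assert res["J_max"] == pytest.approx(best)

    def test_independent_labels_give_small_j(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        assert tf.youden_optimal_cutoff(values, labels)["J_max"] <= 0.3


class TestOddsRatio:
    def test_tug_reconstruction(self):
        res = tf.odds_ratio_2x2([[30, 5], [24, 41]])
        assert res["or"] == pytest.approx(10.25, abs=0.005)
        assert res["ci_low"] == pytest.approx(3.51, abs=0.01)
        assert res["ci_high"] == pytest.approx(29.96, abs=0.01)
        assert res["p"] < 0.001

    def test_chair_stand_reconstruction(self):
        res = tf.odds_ratio_2x2([[27, 3], [27, 43]])
        assert res["or"] == pytest.approx(14.33, abs=0.005)
        assert res["ci_low"] == pytest.approx(3.96, abs=0.01)
        assert res["ci_high"] == pytest.approx(51.87, abs=0.01)

    def test_symmetry_and_reciprocity(self):
        res = tf.odds_ratio_2x2([[8, 2], [2, 8]])
        assert res["or"] == pytest.approx((8 / 2) ** 2)
        swapped = tf.odds_ratio_2x2([[2, 8], [8, 2]])
        assert swapped["or"] == pytest.approx(1 / res["or"])

    def test_independent_table_or_one(self):
        res = tf.odds_ratio_2x2([[10, 20], [5, 10]])
        assert res["or"] == pytest.approx(1.0)

    def test_single_zero_cell_corrected(self):
        res = tf.odds_ratio_2x2([[5, 0], [3, 7]])
        assert res["corrected"]
        assert np.isfinite(res["or"])

    def test_double_zero_undefined(self):
        res = tf.odds_ratio_2x2([[0, 0], [3, 7]])
        assert res["undefined"]
        assert np.isnan(res["or"])
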