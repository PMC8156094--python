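"""Bootstrap-bagging protocol: split integrity, resampling distribution,
aggregation, and the traditional-TUG comparator."""

import numpy as np
import pytest
from scipy import stats

import tugfall as tf


class TestStratifiedSplit:
    def test_balanced_cohort(self, rng):
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        train, test = tf.stratified_split(labels, 0.2, rng)
        assert labels[test].sum() == 10 and len(test) == 20
        assert labels[train].sum() == 40 and len(train) == 80

    def test_study_cohort_rounding(self, rng):
        """53 fallers / 45 non-fallers: round-half-up gives an 11+9 test
        set."""
        labels = np.r_[np.ones(53, int), np.zeros(45, int)]
        train, test = tf.stratified_split(labels, 0.2, rng)
        assert labels[test].sum() == 11
        assert (labels[test] == 0).sum() == 9

    def test_disjoint(self, rng):
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        train, test = tf.stratified_split(labels, 0.2, rng)
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 20

    def test_tiny_class_rejected(self, rng):
        with pytest.raises(ValueError):
            tf.stratified_split([1, 0, 0, 0], 0.2, rng)


class TestBootstrapResample:
    def test_size_and_multiplicity(self, rng):
        draws = tf.bootstrap_resample(np.arange(10), 100, rng)
        assert len(draws) == 1000
        counts = np.bincount(draws, minlength=10)
        assert counts.mean() == 100

    def test_singleton(self, rng):
        np.testing.assert_array_equal(
            tf.bootstrap_resample(np.array([7]), 1, rng), [7])

    def test_multiplicity_binomial(self):
        """Multiplicity of one subject across many resamples follows
        Binomial(1000, 1/10) (chi-square p > 0.01)."""
        counts = []
        for i in range(300):
            rng = np.random.default_rng(i)
            draws = tf.bootstrap_resample(np.arange(10), 100, rng)
            counts.append(np.sum(draws == 0))
        counts = np.asarray(counts)
        edges = [-np.inf, 85, 92, 97, 100, 103, 108, 115, np.inf]
        obs, _ = np.histogram(counts, edges)
        cdf = stats.binom(1000, 0.1).cdf
        probs = np.diff([0] + [cdf(e) for e in edges[1:-1]] + [1])
        res = stats.chisquare(obs, probs * len(counts))
        assert res.pvalue > 0.01


def _duration_cohort(n=30, effect=3.0, seed=0):
    """Per-subject single 'segment' = its feature row; fast SVM bagging."""
    rng = np.random.default_rng(seed)
    labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
    feats = [rng.normal(effect * lab, 1.0, size=(1, 9)) for lab in labels]
    return feats, labels


class TestRunBagging:
    def test_strong_effect_high_auc(self):
        feats, labels = _duration_cohort(n=30, effect=3.0)
        config = tf.BaggingConfig(n_iterations=10, resample_factor=10,
                                  master_seed=4)
        res = tf.run_bagging(feats, labels,
                             lambda s: tf.SvmFallClassifier(random_state=s),
                             config)
        assert res["AUC"]["mean"] >= 0.9

    def test_shuffled_labels_ci_contains_half(self):
        feats, labels = _duration_cohort(n=40, effect=3.0, seed=1)
        shuffled = np.random.default_rng(9).permutation(labels)
        # resplit each iteration so the CI reflects subject-selection
        # noise, not one frozen chance-level test set
        config = tf.BaggingConfig(n_iterations=15, resample_factor=10,
                                  master_seed=4, resplit_each_iter=True)
        res = tf.run_bagging(feats, shuffled,
                             lambda s: tf.SvmFallClassifier(random_state=s),
                             config)
        assert res["AUC"]["ci_low"] <= 0.5 <= res["AUC"]["ci_high"]

    def test_single_iteration_degenerate_ci(self):
        feats, labels = _duration_cohort(n=20, effect=2.0)
        config = tf.BaggingConfig(n_iterations=1, resample_factor=5)
        res = tf.run_bagging(feats, labels,
                             lambda s: tf.SvmFallClassifier(random_state=s),
                             config)
        for metric in ("Acc", "AUC"):
            assert res[metric]["ci_low"] == pytest.approx(
                res[metric]["mean"])
            assert res[metric]["ci_high"] == pytest.approx(
                res[metric]["mean"])

    def test_ci_contains_mean_and_is_ordered(self):
        feats, labels = _duration_cohort(n=30, effect=1.0)
        config = tf.BaggingConfig(n_iterations=12, resample_factor=10,
                                  master_seed=2)
        res = tf.run_bagging(feats, labels,
                             lambda s: tf.SvmFallClassifier(random_state=s),
                             config)
        for metric, s in res.summary.items():
            if np.isnan(s["mean"]):
                continue
            assert s["ci_low"] <= s["mean"] <= s["ci_high"]

    def test_reproducible_given_master_seed(self):
        feats, labels = _duration_cohort(n=20, effect=2.0)
        config = tf.BaggingConfig(n_iterations=3, resample_factor=5,
                                  master_seed=77)
        runs = [tf.run_bagging(
            feats, labels, lambda s: tf.SvmFallClassifier(random_state=s),
            config) for _ in range(2)]
        assert runs[0].per_iteration.equals(runs[1].per_iteration)


class TestTugReferenceBootstrap:
    def test_perfectly_separated_times(self):
        labels = np.r_[np.ones(12, int), np.zeros(12, int)]
        times = np.where(labels == 1, 20.0, 10.0)
        config = tf.BaggingConfig(n_iterations=5, master_seed=1)
        res = tf.tug_reference_bootstrap(times, labels, 14.0, config)
        assert res["Se"]["mean"] == 1.0
        assert res["Sp"]["mean"] == 1.0

    def test_null_times_ci_contains_half(self):
        rng = np.random.default_rng(5)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        times = rng.uniform(8, 20, size=40)  # independent of labels
        config = tf.BaggingConfig(n_iterations=30, master_seed=2)
        res = tf.tug_reference_bootstrap(times, labels, 14.0, config)
        assert res["AUC"]["ci_low"] <= 0.5 <= res["AUC"]["ci_high"]

    def test_multiset_size_is_2000(self):
        labels = np.r_[np.ones(12, int), np.zeros(12, int)]
        times = np.where(labels == 1, 20.0, 10.0)
        config = tf.BaggingConfig(n_iterations=2, master_seed=1)
        res = tf.tug_reference_bootstrap(times, labels, 14.0, config)
        assert res.extra["n_draws"] == 2000
        assert (res.per_iteration["n_test"] == 2000).all()

    def test_too_few_subjects_rejected(self):
        labels = np.r_[np.ones(5, int), np.zeros(20, int)]
        with pytest.raises(ValueError, match="at least 10"):
            tf.tug_reference_bootstrap(np.ones(25), labels)


def test_config_validation():
    with pytest.raises(ValueError):
        tf.BaggingConfig(n_iterations=0)
    with pytest.raises(ValueError):
        tf.BaggingConfig(test_fraction=1.5)
    with pytest.raises(ValueError):
        tf.BaggingConfig(eval_level="window")
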