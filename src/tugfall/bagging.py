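"""Bootstrap-bagging evaluation protocol for the fall-risk classifiers.

Subjects are split once into training and test sets at the subject level
(stratified 80/20, so no subject's windows appear on both sides).  Each
bagging iteration then resamples each set with replacement — by default at
``resample_factor`` times the set size, so one subject can enter many times
and a subject drawn k times contributes its windows k times — trains a
fresh classifier on the training multiset's windows, scores the test
multiset's windows, and records accuracy, sensitivity, specificity,
Youden's J, F1 and AUC.  Summaries report the mean and the percentile
(2.5th/97.5th) 95% CI over iterations, plus the C-statistic inference for
AUC > 0.5.

A training-free comparator mirrors the traditional clinical TUG screen:
each iteration samples 10 fallers + 10 non-fallers, draws 2000 subjects
with replacement from those 20, and classifies by TUG time >= 14 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinmetrics import basic_metrics, c_statistic_test, confusion
from .models import classify

logger = logging.getLogger(__name__)

METRICS = ("Acc", "Se", "Sp", "J", "F1", "AUC")


@dataclass
class BaggingConfig:
    """Protocol settings; defaults follow the screening study."""

    n_iterations: int = 100
    test_fraction: float = 0.2
    resample_factor: int = 100
    master_seed: int = 0
    eval_level: str = "segment"  # or "subject"
    resplit_each_iter: bool = False
    max_redraws: int = 10
    c_stat_method: str = "hanley"

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.resample_factor < 1:
            raise ValueError("resample_factor must be >= 1")
        if self.eval_level not in ("segment", "subject"):
            raise ValueError("eval_level must be 'segment' or 'subject'")


@dataclass
class MetricSummary:
    """Mean and percentile 95% CI per metric, plus AUC inference."""

    summary: dict[str, dict[str, float]]
    per_iteration: pd.DataFrame
    c_statistic: float
    c_statistic_ci: tuple[float, float]
    c_statistic_p: float
    config: BaggingConfig | None = None
    extra: dict = field(default_factory=dict)

    def __getitem__(self, metric: str) -> dict[str, float]:
        return self.summary[metric]

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "c_statistic": self.c_statistic,
            "c_statistic_ci": list(self.c_statistic_ci),
            "c_statistic_p": self.c_statistic_p,
            "n_iterations": int(len(self.per_iteration)),
        }


def stratified_split(labels, test_fraction: float = 0.2,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level stratified split preserving class proportions.

    Per class the test count is ``floor(n_c * test_fraction + 0.5)``
    (round half up).  Raises when a class cannot populate both sets.
    """
    labels = np.asarray(labels, dtype=int)
    rng = rng or np.random.default_rng()
    train, test = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 subjects")
        n_test = int(np.floor(len(idx) * test_fraction + 0.5))
        if n_test < 1 or n_test >= len(idx):
            raise ValueError(
                f"class {cls} too small to populate both sets "
                f"(n={len(idx)}, test_fraction={test_fraction})")
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def bootstrap_resample(subject_idx, factor: int = 100,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform sampling with replacement to ``factor * |set|`` draws."""
    subject_idx = np.asarray(subject_idx)
    if subject_idx.size == 0:
        raise ValueError("subject set is empty")
    rng = rng or np.random.default_rng()
    return rng.choice(subject_idx, size=factor * len(subject_idx),
                      replace=True)


def _multiset_segments(draws, segments_by_subject, labels):
    """Stack windows of a subject multiset; k draws -> k copies."""
    xs, ys, draw_id = [], [], []
    for j, s in enumerate(draws):
        seg = segments_by_subject[s]
        if len(seg) == 0:
            continue
        xs.append(seg)
        ys.append(np.full(len(seg), labels[s]))
        draw_id.append(np.full(len(seg), j))
    if not xs:
        raise ValueError("multiset contains no segments")
    return (np.concatenate(xs), np.concatenate(ys),
            np.concatenate(draw_id))


def _iteration_metrics(scores, y, config) -> dict[str, float]:
    cm = confusion(classify(scores), y)
    m = basic_metrics(cm)
    m["n_test"] = cm.n
    cstat = c_statistic_test(scores, y, method=config.c_stat_method)
    m["AUC"] = cstat["auc"]
    m["z"] = cstat["z"]
    m["p_auc"] = cstat["p_one_sided"]
    return m


def _aggregate(rows: list[dict], config: BaggingConfig,
               extra: dict | None = None) -> MetricSummary:
    df = pd.DataFrame(rows)
    summary = {}
    for metric in METRICS:
        v = df[metric].to_numpy(dtype=float)
        ok = v[np.isfinite(v)]
        summary[metric] = {
            "mean": float(np.mean(ok)) if len(ok) else float("nan"),
            "ci_low": float(np.percentile(ok, 2.5)) if len(ok)
            else float("nan"),
            "ci_high": float(np.percentile(ok, 97.5)) if len(ok)
            else float("nan"),
        }
    z = df["z"].to_numpy(dtype=float)
    z_ok = z[np.isfinite(z)]
    z_mean = float(np.mean(z_ok)) if len(z_ok) else float("nan")
    from scipy.stats import norm
    p = float(norm.sf(z_mean)) if np.isfinite(z_mean) else float("nan")
    return MetricSummary(
        summary=summary, per_iteration=df,
        c_statistic=z_mean,
        c_statistic_ci=(summary["AUC"]["ci_low"], summary["AUC"]["ci_high"]),
        c_statistic_p=p, config=config, extra=extra or {})


def run_bagging(
    segments_by_subject: list[np.ndarray],
    labels,
    model_factory,
    config: BaggingConfig | None = None,
) -> MetricSummary:
    """Run the full bagging protocol for one (model, modality, location).

    Parameters
    ----------
    segments_by_subject : one (n_i, window, channels) array per subject
        (or (n_i, 9) feature rows for the SVM — anything the model eats).
    labels : per-subject 0/1 fall-risk labels.
    model_factory : callable(seed) -> unfitted estimator with
        ``fit`` and ``predict_fall_probability``.
    """
    config = config or BaggingConfig()
    labels = np.asarray(labels, dtype=int)
    if len(segments_by_subject) != len(labels):
        raise ValueError("segments_by_subject and labels length mismatch")
    split_rng = np.random.default_rng([config.master_seed, 0])
    train_idx, test_idx = stratified_split(labels, config.test_fraction,
                                           split_rng)
    rows = []
    for it in range(config.n_iterations):
        rng = np.random.default_rng([config.master_seed, 1, it])
        if config.resplit_each_iter:
            train_idx, test_idx = stratified_split(
                labels, config.test_fraction, rng)
        assert len(np.intersect1d(train_idx, test_idx)) == 0
        train_ms = bootstrap_resample(train_idx, config.resample_factor, rng)
        for attempt in range(config.max_redraws + 1):
            test_ms = bootstrap_resample(test_idx, config.resample_factor,
                                         rng)
            if len(np.unique(labels[test_ms])) == 2:
                break
            logger.info("iteration %d: single-class test multiset, "
                        "redrawing (%d)", it, attempt + 1)
        else:
            raise RuntimeError(
                f"iteration {it}: single-class test multiset after "
                f"{config.max_redraws} redraws")
        if len(np.unique(labels[train_ms])) < 2:
            train_ms = np.concatenate([train_ms, train_idx])
        x_tr, y_tr, _ = _multiset_segments(train_ms, segments_by_subject,
                                           labels)
        x_te, y_te, draw_te = _multiset_segments(
            test_ms, segments_by_subject, labels)
        model = model_factory(int(np.random.default_rng(
            [config.master_seed, 2, it]).integers(2 ** 31)))
        model.fit(x_tr, y_tr)
        p = model.predict_fall_probability(x_te)
        if config.eval_level == "subject":
            # one prediction per draw: mean window probability
            uniq = np.unique(draw_te)
            p = np.array([p[draw_te == u].mean() for u in uniq])
            y_te = np.array([y_te[draw_te == u][0] for u in uniq])
        rows.append(_iteration_metrics(p, y_te, config))
    return _aggregate(rows, config,
                      extra={"train_subjects": train_idx.tolist(),
                             "test_subjects": test_idx.tolist()})


def tug_reference_bootstrap(
    tug_times,
    labels,
    cutoff_s: float = 14.0,
    config: BaggingConfig | None = None,
    n_per_class: int = 10,
    n_draws: int = 2000,
) -> MetricSummary:
    """Training-free bootstrap of the traditional clinical TUG screen.

    Each iteration selects ``n_per_class`` subjects per class without
    replacement, draws ``n_draws`` subjects with replacement from those,
    classifies by ``tug_time >= cutoff_s`` and scores the TUG time itself
    for AUC.  Aggregation matches :func:`run_bagging`.
    """
    config = config or BaggingConfig()
    tug_times = np.asarray(tug_times, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) < n_per_class or len(neg) < n_per_class:
        raise ValueError(
            f"need at least {n_per_class} subjects per class")
    rows = []
    for it in range(config.n_iterations):
        rng = np.random.default_rng([config.master_seed, 3, it])
        chosen = np.concatenate([
            rng.choice(pos, n_per_class, replace=False),
            rng.choice(neg, n_per_class, replace=False)])
        for attempt in range(config.max_redraws + 1):
            draws = rng.choice(chosen, size=n_draws, replace=True)
            if len(np.unique(labels[draws])) == 2:
                break
        else:
            raise RuntimeError("single-class bootstrap sample")
        times = tug_times[draws]
        y = labels[draws]
        pred = (times >= cutoff_s).astype(int)
        cm = confusion(pred, y)
        m = basic_metrics(cm)
        m["n_test"] = cm.n
        cstat = c_statistic_test(times, y, method=config.c_stat_method)
        m["AUC"] = cstat["auc"]
        m["z"] = cstat["z"]
        m["p_auc"] = cstat["p_one_sided"]
        rows.append(m)
    return _aggregate(rows, config, extra={"cutoff_s": cutoff_s,
                                           "n_draws": n_draws})
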