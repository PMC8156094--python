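"""Screening statistics: confusion matrices, ROC/AUC with C-statistic
inference, Youden-optimal cutoffs, clinical-test dichotomization, and
2x2 odds ratios.

Conventions: the faller (high fall-risk) class is positive and encoded 1.
Sensitivity is the fraction of true fallers called fallers; specificity the
fraction of true non-fallers called non-fallers; Youden's J = Se + Sp - 1.
AUC is the Mann-Whitney concordance probability (ties counted 1/2), which
equals the trapezoidal area under the ROC curve.  The C-statistic test
compares AUC against the chance value 0.5 using the Hanley-McNeil standard
error (DeLong variance available as an option).  Odds ratios use the
cross-product with a Woolf (log) confidence interval and the
Haldane-Anscombe 0.5 correction for single zero cells.

Metrics with a zero denominator are returned as NaN, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts with faller as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one "
                             "observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_table(self) -> np.ndarray:
        """2x2 array [[tp, fp], [fn, tn]] (rows: predicted faller / not)."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


@dataclass(frozen=True)
class CutoffRule:
    """A dichotomization rule for a clinical score.

    ``direction`` is explicit, never inferred: ``high_is_faller`` calls
    faller iff value >= cutoff (e.g. TUG time, 14 s or more flags risk);
    ``low_is_faller`` calls faller iff value <= cutoff (e.g. 8 or fewer
    chair stands).  The boundary is inclusive in both directions.
    """

    variable: str
    cutoff: float
    direction: str

    def __post_init__(self):
        if self.direction not in ("high_is_faller", "low_is_faller"):
            raise ValueError("direction must be high_is_faller or "
                             "low_is_faller")


def _as_binary(a, name) -> np.ndarray:
    a = np.asarray(a).astype(int)
    if a.size == 0:
        raise ValueError(f"{name} is empty")
    if not set(np.unique(a)) <= {0, 1}:
        raise ValueError(f"{name} must contain only 0/1 labels")
    return a


def confusion(pred, true) -> ConfusionMatrix:
    """Confusion matrix of predicted vs true fall status (1 = faller)."""
    pred = _as_binary(pred, "pred")
    true = _as_binary(true, "true")
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
    )


def basic_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, F1 and Youden's J.

    A metric whose denominator is zero is NaN (undefined), never 0.
    """
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    acc = ratio(cm.tp + cm.tn, cm.n)
    se = ratio(cm.tp, cm.tp + cm.fn)
    sp = ratio(cm.tn, cm.tn + cm.fp)
    f1 = ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    return {"Acc": acc, "Se": se, "Sp": sp, "F1": f1, "J": se + sp - 1.0}


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_faller > score_non_faller), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = _as_binary(labels, "labels")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(scores, labels) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values: V10_i = P(neg < pos_i) + P(neg == pos_i)/2
    v10 = np.array([(np.sum(neg < x) + 0.5 * np.sum(neg == x)) / n
                    for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m
                    for x in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def c_statistic_test(scores, labels, method: str = "hanley"
                     ) -> dict[str, float]:
    """Test AUC against the chance value 0.5.

    Returns the AUC, its standard error, the z statistic
    ``(AUC - 0.5) / SE``, a one-sided normal p-value for AUC > 0.5, and a
    95% CI ``AUC +/- 1.96 SE`` clipped to [0, 1].  ``method`` selects the
    Hanley-McNeil (default) or DeLong standard error.  With a degenerate
    SE (perfect separation at tiny n) z is +/-inf and the CI collapses; the
    result is flagged via ``degenerate``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _as_binary(labels, "labels")
    auc = roc_auc(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if method == "hanley":
        se = _hanley_mcneil_se(auc, n_pos, n_neg)
    elif method == "delong":
        se = _delong_se(scores, labels)
    else:
        raise ValueError(f"unknown method {method!r}")
    degenerate = se == 0.0
    if degenerate:
        z = float(np.inf) if auc > 0.5 else (
            float(-np.inf) if auc < 0.5 else 0.0)
    else:
        z = (auc - 0.5) / se
    p = float(norm.sf(z)) if np.isfinite(z) else (0.0 if z > 0 else 1.0)
    if z == 0.0:
        p = 0.5
    return {
        "auc": auc, "se": se, "z": float(z),
        "ci_low": float(np.clip(auc - 1.96 * se, 0.0, 1.0)),
        "ci_high": float(np.clip(auc + 1.96 * se, 0.0, 1.0)),
        "p_one_sided": p, "degenerate": bool(degenerate),
    }


def dichotomize(values, rule: CutoffRule) -> np.ndarray:
    """Predicted fall labels from a clinical score under a cutoff rule."""
    values = np.asarray(values, dtype=float)
    if rule.direction == "high_is_faller":
        return (values >= rule.cutoff).astype(int)
    return (values <= rule.cutoff).astype(int)


def youden_optimal_cutoff(values, labels, direction: str = "high_is_faller"
                          ) -> dict:
    """Sweep observed cutoffs and return the one maximizing Youden's J.

    Candidate cutoffs are the sorted unique observed values.  Ties in J are
    broken toward higher sensitivity, then toward the lower cutoff.
    Returns the optimal cutoff, its J, and the full per-cutoff table
    (cutoff, Se, Sp, J).
    """
    values = np.asarray(values, dtype=float)
    labels = _as_binary(labels, "labels")
    if len({0, 1} & set(np.unique(labels))) < 2:
        raise ValueError("both classes must be present")
    candidates = np.unique(values)
    rows = []
    for c in candidates:
        rule = CutoffRule("sweep", float(c), direction)
        m = basic_metrics(confusion(dichotomize(values, rule), labels))
        rows.append((float(c), m["Se"], m["Sp"], m["J"]))
    best = max(rows, key=lambda r: (r[3], r[1], -r[0]))
    return {"cutoff": best[0], "J_max": best[3], "Se": best[1],
            "Sp": best[2], "table": rows}


def odds_ratio_2x2(table) -> dict[str, float]:
    """Odds ratio of a 2x2 table with Woolf 95% CI and two-sided p.

    ``table`` is [[a, b], [c, d]] (or a :class:`ConfusionMatrix`, read as
    [[tp, fp], [fn, tn]]).  OR = ad / bc.  A single zero cell triggers the
    Haldane-Anscombe 0.5 correction (flagged via ``corrected``); two zero
    cells in one row or column make the OR undefined and all outputs NaN.
    """
    if isinstance(table, ConfusionMatrix):
        table = table.as_table()
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative cells")
    a, b, c, d = t.ravel()
    zeros = t == 0
    undefined = any(zeros[i, :].all() for i in range(2)) or \
        any(zeros[:, j].all() for j in range(2))
    if undefined:
        nan = float("nan")
        return {"or": nan, "ci_low": nan, "ci_high": nan, "p": nan,
                "corrected": False, "undefined": True}
    corrected = bool(zeros.any())
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    z = log_or / se
    return {
        "or": float(or_),
        "ci_low": float(np.exp(log_or - 1.96 * se)),
        "ci_high": float(np.exp(log_or + 1.96 * se)),
        "p": float(2 * norm.sf(abs(z))),
        "corrected": corrected, "undefined": False,
    }
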