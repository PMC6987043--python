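"""Per-molecule aggregation and imbalance-aware evaluation.

An image classifier emits one active-class probability per snapshot; the
median over a molecule's snapshots is that molecule's representative score.
Molecule-level scores against experimental labels yield a confusion matrix
at a cutoff and the derived metric bundle used for imbalanced screening
data:

    sensitivity = TP / (TP + FN)            specificity = TN / (TN + FP)
    BAC  = (sensitivity + specificity) / 2
    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)              recall = sensitivity
    F = 2 * recall * precision / (recall + precision)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus the ROC AUC, which equals the Mann-Whitney rank statistic
P(score_pos > score_neg) + 0.5 * P(tie). Run-level comparisons use the
two-sided Mann-Whitney U test with Bonferroni correction and
difference-of-means with a Welch 95% confidence interval.

Any metric whose denominator is zero is reported as ``None`` (undefined),
never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RunComparison",
    "aggregate_median",
    "confusion_at_cutoff",
    "metrics",
    "roc_auc",
    "optimal_cutoff",
    "compare_runs",
    "delta_ci",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricsReport:
    """Confusion-derived metrics; undefined fields are None."""

    sensitivity: float | None
    specificity: float | None
    bac: float | None
    accuracy: float | None
    precision: float | None
    recall: float | None
    f_value: float | None
    mcc: float | None
    auc: float | None = None
    cutoff: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def aggregate_median(image_probs: Sequence[float], molecule_id: str = "") -> float:
    """Median of a molecule's per-image probabilities.

    Even counts take the mean of the two central values (the common case for
    8-image snapshot sets). Invariant to the order of the list.
    """
    if len(image_probs) == 0:
        raise ValueError(f"no image probabilities for molecule {molecule_id!r}")
    return float(np.median(np.asarray(image_probs, dtype=float)))


def confusion_at_cutoff(
    preds: Sequence[float], labels: Sequence[int], cutoff: float
) -> ConfusionMatrix:
    """Confusion matrix with prediction positive iff prob >= cutoff."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels length mismatch")
    if preds.size == 0:
        raise ValueError("empty prediction list")
    pos = preds >= cutoff
    tp = int(np.sum(pos & (labels == 1)))
    fp = int(np.sum(pos & (labels == 0)))
    fn = int(np.sum(~pos & (labels == 1)))
    tn = int(np.sum(~pos & (labels == 0)))
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics(cm: ConfusionMatrix, cutoff: float | None = None) -> MetricsReport:
    """Metric bundle from a confusion matrix (AUC filled separately).

    MCC uses the square root of the denominator product, the standard form
    of the statistic.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fn, tn, fp = cm.tp, cm.fn, cm.tn, cm.fp
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    bac = None if sens is None or spec is None else (sens + spec) / 2.0
    acc = _ratio(tp + tn, cm.total)
    prec = _ratio(tp, tp + fp)
    rec = sens
    if prec is None or rec is None or prec + rec == 0:
        f = None
    else:
        f = 2.0 * rec * prec / (rec + prec)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        bac=bac,
        accuracy=acc,
        precision=prec,
        recall=rec,
        f_value=f,
        mcc=mcc,
        cutoff=cutoff,
    )


def roc_auc(preds: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC = P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(preds, dtype=float)))


def optimal_cutoff(preds: Sequence[float], labels: Sequence[int]) -> float:
    """Cutoff maximizing balanced accuracy.

    Candidates are midpoints of adjacent distinct scores plus sentinels just
    below the minimum and just above the maximum; ties in BAC go to the
    lowest cutoff. Equivalent to maximizing Youden's J.
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("optimal_cutoff requires both classes present")
    uniq = np.unique(preds)
    candidates = [uniq[0] - 1e-9]
    candidates += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    candidates += [uniq[-1] + 1e-9]
    best_c, best_bac = None, -1.0
    for c in candidates:
        rep = metrics(confusion_at_cutoff(preds, labels, c))
        if rep.bac is not None and rep.bac > best_bac + 1e-12:
            best_bac, best_c = rep.bac, c
    return float(best_c)


@dataclass
class RunComparison:
    u_statistic: float
    p_value: float
    p_corrected: float
    delta: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_corrected < 0.05


def compare_runs(
    metric_values_a: Sequence[float],
    metric_values_b: Sequence[float],
    n_comparisons: int = 1,
) -> RunComparison:
    """Two-sided Mann-Whitney U test with Bonferroni correction.

    The exact null distribution is used for small tie-free samples and the
    normal approximation otherwise (scipy's "auto" policy). Fully degenerate
    input (every value identical across both samples) reports p = 1.
    """
    a = np.asarray(metric_values_a, dtype=float)
    b = np.asarray(metric_values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs length >= 3")
    if np.all(a == a[0]) and np.all(b == a[0]):
        u = len(a) * len(b) / 2.0
        p = 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        u, p = float(res.statistic), float(res.pvalue)
    pc = min(1.0, p * int(n_comparisons))
    d, lo, hi = delta_ci(a, b)
    return RunComparison(
        u_statistic=u, p_value=p, p_corrected=pc, delta=d, ci_low=lo, ci_high=hi
    )


def delta_ci(
    one: Sequence[float], rest_pooled: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float]:
    """Difference of means with a Welch (unequal-variance) t interval."""
    a = np.asarray(one, dtype=float)
    b = np.asarray(rest_pooled, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs length >= 2 for a CI")
    delta = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    se = math.sqrt(va + vb)
    if se == 0:
        return delta, delta, delta
    df = (va + vb) ** 2 / (
        va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
    )
    t = stats.t.ppf(0.5 + confidence / 2.0, df)
    return delta, delta - t * se, delta + t * se


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den
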