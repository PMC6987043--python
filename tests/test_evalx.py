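"""Metric suite against hand and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import snapqsar as sq
from snapqsar.evalx import ConfusionMatrix, confusion_at_cutoff, delta_ci, metrics


def brute_force_auc(preds, labels):
    """Oracle: count concordant positive-negative pairs, ties worth 1/2."""
    pos = [p for p, l in zip(preds, labels) if l == 1]
    neg = [p for p, l in zip(preds, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# --- median aggregation -----------------------------------------------------

@pytest.mark.parametrize(
    "probs, expected",
    [([0.7], 0.7), ([0.2, 0.8, 0.6], 0.6), ([0.1, 0.2, 0.8, 0.9], 0.5)],
)
def test_aggregate_median_oracles(probs, expected):
    assert sq.aggregate_median(probs) == pytest.approx(expected)


def test_aggregate_median_permutation_invariant():
    rng = np.random.default_rng(0)
    probs = list(rng.random(8))
    base = sq.aggregate_median(probs)
    for s in range(20):
        shuffled = list(np.random.default_rng(s).permutation(probs))
        assert sq.aggregate_median(shuffled) == pytest.approx(base)


def test_aggregate_median_empty_carries_id():
    with pytest.raises(ValueError, match="mol42"):
        sq.aggregate_median([], molecule_id="mol42")


# --- confusion and metrics --------------------------------------------------

def test_confusion_cutoff_cases():
    preds = [0.9, 0.2, 0.6, 0.4]
    labels = [1, 0, 1, 0]
    cm = confusion_at_cutoff(preds, labels, 0.5)
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)
    cm0 = confusion_at_cutoff(preds, labels, 0.0)
    assert cm0.fn == 0 and cm0.tn == 0
    cmhi = confusion_at_cutoff(preds, labels, 0.91)
    assert cmhi.tp == 0 and cmhi.fp == 0


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        confusion_at_cutoff([0.5], [1, 0], 0.5)


def test_worked_example_metrics():
    preds, labels, cm, rep = sq.worked_confusion_example()
    assert confusion_at_cutoff(preds, labels, 0.5) == cm
    assert rep.sensitivity == pytest.approx(0.75)
    assert rep.specificity == pytest.approx(0.6667, abs=5e-5)
    assert rep.bac == pytest.approx(0.7083, abs=5e-5)
    assert rep.accuracy == pytest.approx(0.7)
    assert rep.precision == pytest.approx(0.6)
    assert rep.f_value == pytest.approx(0.6667, abs=5e-5)
    assert rep.mcc == pytest.approx(0.4082, abs=5e-5)
    assert rep.recall == rep.sensitivity


def test_perfect_and_null_confusions():
    perfect = metrics(ConfusionMatrix(tp=5, fn=0, tn=7, fp=0))
    for field in ("sensitivity", "specificity", "bac", "accuracy", "precision", "f_value", "mcc"):
        assert getattr(perfect, field) == pytest.approx(1.0)
    null = metrics(ConfusionMatrix(tp=2, fn=2, tn=2, fp=2))
    assert null.mcc == pytest.approx(0.0)


def test_undefined_metrics_are_none_not_zero():
    # no positives at all: sensitivity is 0/0, undefined — not silently 0
    rep = metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=5))
    assert rep.sensitivity is None
    assert rep.bac is None
    assert rep.mcc is None  # (TP+FN) factor is zero
    assert rep.precision == pytest.approx(0.0)  # 0/5 is defined
    assert rep.specificity == pytest.approx(0.5)
    # nothing predicted positive: precision is 0/0, undefined
    rep2 = metrics(ConfusionMatrix(tp=0, fn=5, tn=5, fp=0))
    assert rep2.precision is None
    assert rep2.f_value is None


@settings(max_examples=250, derandomize=True, deadline=None)
@given(
    tp=st.integers(0, 50), fn=st.integers(0, 50),
    tn=st.integers(0, 50), fp=st.integers(0, 50),
)
def test_metric_identities_on_random_confusions(tp, fn, tn, fp):
    """BAC is the mean of sens/spec; F the harmonic mean of prec/recall;
    MCC's sign is the sign of TP*TN - FP*FN."""
    if tp + fn + tn + fp == 0:
        return
    rep = metrics(ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp))
    if rep.sensitivity is not None and rep.specificity is not None:
        assert rep.bac == pytest.approx((rep.sensitivity + rep.specificity) / 2)
    if rep.f_value is not None:
        assert rep.f_value == pytest.approx(
            2 / (1 / rep.precision + 1 / rep.recall)
        )
    if rep.mcc is not None:
        assert math.copysign(1, rep.mcc) == math.copysign(1, tp * tn - fp * fn) or rep.mcc == 0
        assert -1 <= rep.mcc <= 1
    for field in ("sensitivity", "specificity", "bac", "accuracy", "precision", "f_value"):
        v = getattr(rep, field)
        assert v is None or 0 <= v <= 1


# --- ROC AUC ----------------------------------------------------------------

def test_auc_hand_oracle():
    assert sq.roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)
    assert sq.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        sq.roc_auc([0.1, 0.9], [1, 1])


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_auc_equals_brute_force_pairs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 200))
    preds = rng.integers(0, 10, size=n) / 10.0  # coarse grid forces ties
    labels = rng.integers(0, 2, size=n)
    if len(set(labels.tolist())) < 2:
        return
    assert sq.roc_auc(preds, labels) == pytest.approx(
        brute_force_auc(preds, labels), abs=1e-12
    )


def test_auc_null_monte_carlo():
    rng = np.random.default_rng(123)
    preds = rng.random(1000)
    labels = rng.integers(0, 2, size=1000)
    assert abs(sq.roc_auc(preds, labels) - 0.5) < 0.05


def test_label_swap_symmetry():
    rng = np.random.default_rng(5)
    preds = rng.random(60)
    labels = rng.integers(0, 2, size=60)
    swapped_preds = 1 - preds
    swapped_labels = 1 - labels
    assert sq.roc_auc(swapped_preds, swapped_labels) == pytest.approx(
        sq.roc_auc(preds, labels)
    )
    c = sq.optimal_cutoff(preds, labels)
    m = metrics(confusion_at_cutoff(preds, labels, c))
    # prob >= cutoff is boundary-inclusive, so mirror the cutoff just above 1-c
    ms = metrics(confusion_at_cutoff(swapped_preds, swapped_labels, (1 - c) + 1e-12))
    assert ms.mcc == pytest.approx(m.mcc)
    assert ms.sensitivity == pytest.approx(m.specificity)
    assert ms.specificity == pytest.approx(m.sensitivity)


# --- cutoff selection -------------------------------------------------------

def test_optimal_cutoff_separable():
    c = sq.optimal_cutoff([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
    assert 0.4 < c < 0.8
    rep = metrics(confusion_at_cutoff([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0], c))
    assert rep.bac == pytest.approx(1.0)


def test_optimal_cutoff_all_tied_scores():
    c = sq.optimal_cutoff([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
    rep = metrics(confusion_at_cutoff([0.5] * 4, [1, 0, 1, 0], c))
    assert rep.bac == pytest.approx(0.5)


# --- run comparisons --------------------------------------------------------

def test_mann_whitney_exact_oracle():
    """Fully separated 3-vs-3 samples: U = 0 and exact two-sided p = 0.1
    (2 of the C(6,3) = 20 equally likely rank assignments are as extreme)."""
    res = sq.compare_runs([1, 2, 3], [10, 11, 12], n_comparisons=1)
    assert res.u_statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(0.1)


def test_bonferroni_correction():
    res = sq.compare_runs([1, 2, 3], [10, 11, 12], n_comparisons=9)
    assert res.p_corrected == pytest.approx(min(1.0, 9 * res.p_value))
    assert res.p_corrected >= res.p_value


def test_identical_lists_not_significant():
    res = sq.compare_runs([0.5] * 5, [0.5] * 5, n_comparisons=9)
    assert res.p_corrected == 1.0
    assert not res.significant


def test_delta_ci_welch_closed_form():
    one, rest = [2.0, 4.0], [1.0, 3.0]
    delta, lo, hi = delta_ci(one, rest)
    # hand evaluation of the Welch interval
    va, vb = 2.0 / 2, 2.0 / 2  # s^2/n for both samples
    se = math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 + vb**2)  # (n-1)=1 each
    from scipy import stats

    t = stats.t.ppf(0.975, df)
    assert delta == pytest.approx(1.0)
    assert lo == pytest.approx(1.0 - t * se, abs=1e-6)
    assert hi == pytest.approx(1.0 + t * se, abs=1e-6)


def test_delta_ci_identical_samples_straddles_zero():
    delta, lo, hi = delta_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert delta == pytest.approx(0.0)
    assert lo <= 0 <= hi


def test_delta_ci_constant_shift():
    delta, lo, hi = delta_ci([5.001, 5.0], [1.0, 1.001])
    assert delta == pytest.approx(4.0, abs=1e-2)
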