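import json

import numpy as np
import pandas as pd
import pytest
from sklearn import metrics as skm

from herdsense import evaluation
from herdsense.io import CLASSES

# Confusion matrix of the reference CNN on the original farm recordings
# (rows = actual, columns = predicted), used as printed input data.
FARM_CONFUSION = pd.DataFrame(
    [[7896, 147, 12, 1, 136],
     [185, 8352, 21, 7, 292],
     [12, 18, 13058, 43, 10],
     [20, 23, 96, 4793, 69],
     [138, 337, 9, 19, 6641]],
    index=list(CLASSES), columns=list(CLASSES))


def test_perfect_predictions_are_diagonal():
    labels = np.repeat(CLASSES, 2)
    cm = evaluation.confusion(labels, labels)
    assert np.trace(cm.to_numpy()) == 10
    assert cm.to_numpy().sum() == 10


def test_hand_tally():
    cm = evaluation.confusion(["feeding", "feeding", "moving"],
                              ["feeding", "moving", "moving"])
    assert cm.loc["feeding", "feeding"] == 1
    assert cm.loc["feeding", "moving"] == 1
    assert cm.loc["moving", "moving"] == 1
    assert cm.to_numpy().sum() == 3


def test_confusion_input_validation():
    with pytest.raises(ValueError, match="length"):
        evaluation.confusion(["feeding"], ["feeding", "moving"])
    with pytest.raises(ValueError, match="vocabulary"):
        evaluation.confusion(["feeding"], ["flying"])


def test_farm_matrix_reproduces_printed_metrics():
    """The reference two-decimal metric table follows from its own
    confusion matrix."""
    report = evaluation.metrics(FARM_CONFUSION)
    r2 = evaluation.round2
    expected = {
        "feeding": (0.96, 0.96, 0.96, 8192),
        "moving": (0.94, 0.94, 0.94, 8857),
        "resting": (0.99, 0.99, 0.99, 13141),
        "ruminating": (0.99, 0.96, 0.97, 5001),
        "standing_still": (0.93, 0.93, 0.93, 7144),
    }
    for c in report.per_class:
        p, r, f1, support = expected[c.label]
        assert r2(c.precision) == p, c.label
        assert r2(c.recall) == r, c.label
        assert r2(c.f1) == f1, c.label
        assert c.support == support, c.label
    assert report.total == 42335
    assert r2(report.accuracy) == 0.96
    for v in (report.macro_precision, report.macro_recall, report.macro_f1,
              report.weighted_precision, report.weighted_recall,
              report.weighted_f1):
        assert r2(v) == 0.96


def test_exact_reference_ratios():
    report = evaluation.metrics(FARM_CONFUSION)
    rum = next(c for c in report.per_class if c.label == "ruminating")
    assert rum.precision == pytest.approx(4793 / 4863)
    assert rum.recall == pytest.approx(4793 / 5001)
    assert report.accuracy == pytest.approx(40740 / 42335)


def test_agrees_with_sklearn_on_random_labels():
    rng = np.random.default_rng(0)
    for _ in range(20):
        actual = rng.choice(CLASSES, size=200)
        pred = rng.choice(CLASSES, size=200)
        report = evaluation.metrics(evaluation.confusion(actual, pred))
        p, r, f, s = skm.precision_recall_fscore_support(
            actual, pred, labels=list(CLASSES), zero_division=0)
        for i, c in enumerate(report.per_class):
            assert c.precision == pytest.approx(p[i])
            assert c.recall == pytest.approx(r[i])
            assert c.f1 == pytest.approx(f[i])
            assert c.support == s[i]
        assert report.accuracy == pytest.approx(
            skm.accuracy_score(actual, pred))
        assert report.macro_f1 == pytest.approx(
            skm.f1_score(actual, pred, labels=list(CLASSES),
                         average="macro", zero_division=0))
        assert report.weighted_f1 == pytest.approx(
            skm.f1_score(actual, pred, labels=list(CLASSES),
                         average="weighted", zero_division=0))


def test_micro_average_identity():
    """Micro precision = micro recall = accuracy, for any matrix."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        m = pd.DataFrame(rng.integers(0, 50, size=(5, 5)),
                         index=list(CLASSES), columns=list(CLASSES))
        report = evaluation.metrics(m)
        tp = sum(c.tp for c in report.per_class)
        fp = sum(c.fp for c in report.per_class)
        fn = sum(c.fn for c in report.per_class)
        assert tp / (tp + fp) == pytest.approx(report.accuracy)
        assert tp / (tp + fn) == pytest.approx(report.accuracy)


def test_equal_supports_make_weighted_equal_macro():
    rng = np.random.default_rng(9)
    m = rng.integers(1, 20, size=(5, 5))
    m = m - np.diag(np.diag(m)) + np.diag([0] * 5)
    np.fill_diagonal(m, 100 - m.sum(axis=1))  # all row sums 100
    report = evaluation.metrics(pd.DataFrame(m, index=list(CLASSES),
                                             columns=list(CLASSES)))
    assert report.weighted_precision == pytest.approx(
        report.macro_precision)
    assert report.weighted_f1 == pytest.approx(report.macro_f1)


def test_absent_class_flagged_not_crashing():
    m = pd.DataFrame(np.zeros((5, 5), dtype=int), index=list(CLASSES),
                     columns=list(CLASSES))
    m.loc["feeding", "feeding"] = 10  # only one class ever appears
    report = evaluation.metrics(m)
    resting = next(c for c in report.per_class if c.label == "resting")
    assert resting.precision == 0.0
    assert "precision" in resting.undefined
    assert "recall" in resting.undefined


def test_round_half_up():
    assert evaluation.round2(0.005) == 0.01
    assert evaluation.round2(0.125) == 0.13
    assert evaluation.round2(0.9649) == 0.96
    assert evaluation.round2(0.965) == 0.97


def test_render_consistency():
    report = evaluation.metrics(FARM_CONFUSION)
    text, js = evaluation.report_render(report)
    data = json.loads(js)
    assert f"{evaluation.round2(data['accuracy']):.2f}" in text
    assert "0.96" in text
    # perfect classifier prints 1.00 everywhere
    perfect = evaluation.confusion(list(CLASSES), list(CLASSES))
    ptext, _ = evaluation.report_render(evaluation.metrics(perfect))
    assert ptext.count("1.00") >= 15
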