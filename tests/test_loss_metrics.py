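"""Dice loss, confusion counts, the six metrics, and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvseg.metrics import (ConfusionCounts, aggregate, compute_metrics,
                           confusion, dice_loss)
from lvseg.nn import Tensor


def test_dice_loss_closed_forms():
    a = np.array([[1.0, 1.0], [1.0, 0.0]])
    assert dice_loss(a, a, smooth=0.0) == pytest.approx(0.0)
    disjoint = 1.0 - a
    assert dice_loss(a, disjoint, smooth=0.0) == pytest.approx(1.0)
    pred = np.array([[1.0, 1.0], [0.0, 1.0]])
    # overlap 2, |g|+|s| = 6 -> 1 - 4/6
    assert dice_loss(pred, a, smooth=0.0) == pytest.approx(1.0 / 3.0)


def test_dice_loss_soft_hard_consistency(rng):
    for _ in range(20):
        target = (rng.uniform(size=(16, 16)) > 0.6).astype(float)
        pred = (rng.uniform(size=(16, 16)) > 0.5).astype(float)
        loss = dice_loss(pred, target, smooth=0.0)
        dsc = compute_metrics(confusion(pred.astype(int), target.astype(int)))["dsc"]
        assert 1.0 - loss == pytest.approx(dsc, abs=1e-12)


def test_dice_loss_bounds_and_monotone_tp(rng):
    target = np.zeros((8, 8))
    target[2:6, 2:6] = 1.0
    pred = np.zeros((8, 8))
    prev = dice_loss(pred, target, smooth=1.0)
    for (i, j) in [(2, 2), (2, 3), (3, 3), (4, 4), (5, 5)]:
        pred[i, j] = 1.0  # add a true-positive pixel
        cur = dice_loss(pred, target, smooth=1.0)
        assert cur <= prev
        prev = cur
    assert 0.0 <= cur <= 1.0


def test_dice_loss_is_differentiable_tensor_path(rng):
    p = Tensor(rng.uniform(0.01, 0.99, size=(2, 1, 8, 8)), requires_grad=True)
    t = (rng.uniform(size=(2, 1, 8, 8)) > 0.5).astype(float)
    loss = dice_loss(p, t, smooth=1.0)
    loss.backward()
    assert p.grad is not None and np.isfinite(p.grad).all()


def test_dice_loss_errors():
    with pytest.raises(ValueError):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 2)))
    with pytest.raises(ValueError):
        dice_loss(np.zeros((2, 2)), np.full((2, 2), 0.5))


def test_confusion_contracts():
    t = np.zeros((4, 4), dtype=int)
    t[:2, :2] = 1
    c = confusion(t, t)
    assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 12)
    c = confusion(np.zeros_like(t), t)
    assert (c.tp, c.fn) == (0, 4)
    pred = t.copy()
    pred[0, 0] = 0   # one miss
    pred[3, 3] = 1   # one false alarm
    c = confusion(pred, t)
    assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 1, 11)
    assert c.total == 16
    with pytest.raises(ValueError):
        confusion(t * 2, t)


def test_compute_metrics_hand_example():
    m = compute_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=12))
    assert m["dsc"] == pytest.approx(0.6667, abs=5e-5)
    assert m["iou"] == pytest.approx(0.5)
    assert m["accuracy"] == pytest.approx(0.875)
    assert m["recall"] == pytest.approx(0.6667, abs=5e-5)
    assert m["precision"] == pytest.approx(0.6667, abs=5e-5)
    assert m["specificity"] == pytest.approx(0.9231, abs=5e-5)


def test_perfect_prediction_scores_one():
    m = compute_metrics(ConfusionCounts(tp=7, fp=0, fn=0, tn=9))
    assert all(v == 1.0 for v in m.values())


def test_degenerate_zero_over_zero_conventions():
    # empty target, empty prediction: perfect agreement
    m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=16))
    assert m["dsc"] == m["iou"] == m["recall"] == m["precision"] == 1.0
    # empty target, non-empty prediction
    m = compute_metrics(ConfusionCounts(tp=0, fp=3, fn=0, tn=13))
    assert m["dsc"] == m["iou"] == m["recall"] == 0.0
    assert m["precision"] == 0.0


@settings(deadline=None, max_examples=200, derandomize=True)
@given(tp=st.integers(0, 10**6), fp=st.integers(0, 10**6),
       fn=st.integers(0, 10**6), tn=st.integers(0, 10**6))
def test_dsc_iou_identity_and_ranges(tp, fp, fn, tn):
    m = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
    assert abs(m["dsc"] - 2 * m["iou"] / (1 + m["iou"])) < 1e-12
    assert all(0.0 <= v <= 1.0 for v in m.values())


def test_aggregate_single_record():
    rec = compute_metrics(ConfusionCounts(5, 1, 2, 8))
    rep = aggregate([rec])
    assert rep.sd["dsc"] == 0.0
    assert rep.mean["dsc"] == rec["dsc"]
    assert rep.boxplot["dsc"]["outliers"] == []


def test_aggregate_hand_mean_sd():
    recs = [{m: v for m in ("dsc", "iou", "accuracy", "recall", "precision",
                            "specificity")} for v in (0.8, 0.9, 1.0)]
    rep = aggregate(recs)
    assert rep.mean["dsc"] == pytest.approx(0.9)
    assert rep.sd["dsc"] == pytest.approx(0.1)  # sample (n-1) SD


def test_aggregate_boxplot_matches_percentile_oracle(rng):
    values = rng.uniform(size=100)
    recs = [{m: float(v) for m in ("dsc", "iou", "accuracy", "recall",
                                   "precision", "specificity")} for v in values]
    rep = aggregate(recs)
    box = rep.boxplot["iou"]
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    assert box["q1"] == pytest.approx(q1)
    assert box["median"] == pytest.approx(med)
    assert box["q3"] == pytest.approx(q3)
    assert box["min"] == pytest.approx(values.min())
    assert box["max"] == pytest.approx(values.max())
    iqr = q3 - q1
    expected_out = values[(values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)]
    assert sorted(box["outliers"]) == sorted(float(v) for v in expected_out)


def test_aggregate_empty_raises():
    with pytest.raises(ValueError):
        aggregate([])


def test_report_csv_roundtrip(tmp_path, rng):
    recs = [compute_metrics(ConfusionCounts(5, i, 2, 8)) for i in range(4)]
    rep = aggregate(recs)
    rep.to_csv(tmp_path / "r.csv")
    import pandas as pd
    back = pd.read_csv(tmp_path / "r.csv", index_col=0)
    assert len(back) == 6  # 4 images + mean + sd rows
    assert rep.summary().splitlines()[0].startswith("metric")
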