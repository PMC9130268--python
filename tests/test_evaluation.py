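"""Evaluation metrics, fold aggregation, report matrices and the ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mscolo.evaluation import (AnovaResult, ConfusionCounts, MetricSet,
                               aggregate_folds, anova_compare, auc_from_scores,
                               build_report, fold_frame, metrics_from_counts,
                               report_from_frame)
from mscolo.types import ParameterError

counts_strategy = st.tuples(*[st.integers(0, 500)] * 4).filter(
    lambda c: sum(c) > 0)


# ---------------------------------------------------------------------------
# scalar metric oracle


def _metrics_oracle(tp, tn, fp, fn):
    """Independent scalar evaluation of the accuracy formulas."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    acc2 = (sen + spe) / 2
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return acc, acc2, mcc


def test_perfect_classifier_scores_one():
    ms = metrics_from_counts(ConfusionCounts(30, 50, 0, 0))
    assert ms.acc == ms.acc2 == ms.mcc == 1.0


def test_symmetric_counts_force_chance_level():
    ms = metrics_from_counts(ConfusionCounts(7, 7, 7, 7))
    assert ms.acc == ms.acc2 == 0.5
    assert ms.mcc == 0.0


def test_worked_confusion_table():
    ms = metrics_from_counts(ConfusionCounts(40, 30, 10, 20))
    acc, acc2, mcc = _metrics_oracle(40, 30, 10, 20)
    assert ms.acc == pytest.approx(acc)
    assert ms.acc2 == pytest.approx(acc2)
    assert ms.mcc == pytest.approx(mcc)


def test_all_zero_counts_raise():
    with pytest.raises(ParameterError):
        metrics_from_counts(ConfusionCounts(0, 0, 0, 0))


@settings(max_examples=300, derandomize=True)
@given(counts_strategy)
def test_metrics_match_oracle_and_bounds(counts):
    tp, tn, fp, fn = counts
    ms = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
    acc, acc2, mcc = _metrics_oracle(tp, tn, fp, fn)
    assert ms.acc == pytest.approx(acc)
    assert ms.acc2 == pytest.approx(acc2)
    assert ms.mcc == pytest.approx(mcc)
    assert 0.0 <= ms.acc <= 1.0 and 0.0 <= ms.acc2 <= 1.0
    assert -1.0 <= ms.mcc <= 1.0


@settings(max_examples=200, derandomize=True)
@given(counts_strategy)
def test_label_swap_and_prediction_flip_symmetries(counts):
    """Renaming the two classes (TP<->TN, FP<->FN) exchanges Sen with Spe
    and leaves MCC and ACC2 fixed; inverting the predictions (TP<->FN,
    TN<->FP) negates MCC."""
    tp, tn, fp, fn = counts
    ms = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
    renamed = metrics_from_counts(ConfusionCounts(tn, tp, fn, fp))
    assert renamed.mcc == pytest.approx(ms.mcc)
    assert renamed.sen == pytest.approx(ms.spe)
    assert renamed.spe == pytest.approx(ms.sen)
    assert renamed.acc2 == pytest.approx(ms.acc2)
    inverted = metrics_from_counts(ConfusionCounts(fn, fp, tn, tp))
    assert inverted.mcc == pytest.approx(-ms.mcc)


def test_mcc_equals_pearson_correlation_of_binary_vectors():
    rng = np.random.default_rng(0)
    for _ in range(50):
        y = rng.integers(0, 2, 60)
        pred = rng.integers(0, 2, 60)
        tp = int(np.sum((y == 1) & (pred == 1)))
        tn = int(np.sum((y == 0) & (pred == 0)))
        fp = int(np.sum((y == 0) & (pred == 1)))
        fn = int(np.sum((y == 1) & (pred == 0)))
        ms = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
        if y.std() == 0 or pred.std() == 0:
            assert ms.mcc == 0.0
        else:
            assert ms.mcc == pytest.approx(np.corrcoef(y, pred)[0, 1])


# ---------------------------------------------------------------------------
# AUC


def _auc_oracle(scores, labels):
    """Brute-force enumeration over positive-negative pairs; ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfectly_separated_scores_give_auc_one():
    assert auc_from_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0


def test_identical_scores_give_half():
    assert auc_from_scores([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)


def test_auc_with_tie_matches_pair_enumeration():
    scores = [0.9, 0.7, 0.7, 0.4, 0.3, 0.1]
    labels = [1, 1, 0, 0, 1, 0]
    assert auc_from_scores(scores, labels) == pytest.approx(
        _auc_oracle(scores, labels))


def test_auc_random_instances_match_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = rng.integers(4, 30)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert auc_from_scores(scores, labels) == pytest.approx(
            _auc_oracle(scores, labels))


def test_auc_single_class_is_missing():
    assert math.isnan(auc_from_scores([0.1, 0.9], [1, 1]))


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores = rng.random(40)
    labels = rng.integers(0, 2, 40)
    base = auc_from_scores(scores, labels)
    assert auc_from_scores(np.exp(3 * scores), labels) == pytest.approx(base)
    assert auc_from_scores(np.log(scores + 1e-9), labels) == pytest.approx(base)


# ---------------------------------------------------------------------------
# fold aggregation and reports


class _Fold:
    def __init__(self, animal_id, group, tp, tn, fp, fn, scores, y):
        self.animal_id = animal_id
        self.model_group = group
        self.classifier = "RF"
        self.tp, self.tn, self.fp, self.fn = tp, tn, fp, fn
        self.scores = np.asarray(scores, dtype=float)
        self.y_true = np.asarray(y)


def _fold(animal="m0", group="spontaneous", tp=10, tn=10, fp=5, fn=5):
    n = tp + tn + fp + fn
    y = np.r_[np.ones(tp + fn, int), np.zeros(tn + fp, int)]
    scores = np.r_[np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)]
    return _Fold(animal, group, tp, tn, fp, fn, scores, y)


def test_identical_folds_aggregate_to_common_value():
    folds = [_fold(), _fold("m1")]
    ms = aggregate_folds(folds)
    single = metrics_from_counts(ConfusionCounts(10, 10, 5, 5))
    assert ms.mcc == pytest.approx(single.mcc)
    assert ms.acc == pytest.approx(single.acc)


def test_fold_mean_is_unweighted():
    f1 = _fold(tp=10, tn=10, fp=5, fn=5)       # MCC ~ 0.33 on 30 pixels
    f2 = _fold("m1", tp=100, tn=100, fp=0, fn=0)  # MCC 1.0 on 200 pixels
    ms = aggregate_folds([f1, f2])
    m1 = metrics_from_counts(ConfusionCounts(10, 10, 5, 5)).mcc
    assert ms.mcc == pytest.approx((m1 + 1.0) / 2)


def test_report_matrices_have_classifier_by_metric_shape():
    results = {
        arm: {clf: [_fold("m0", "spontaneous"), _fold("m1", "inflammation")]
              for clf in ("RF", "RB", "AB", "SVM_lin", "SVM_gauss")}
        for arm in ("with_spatial", "without_spatial")}
    report = build_report(results)
    for arm in ("with_spatial", "without_spatial"):
        mat = report[f"all_{arm}"]
        assert mat.shape == (5, 4)
        assert list(mat.columns) == ["ACC", "ACC2", "AUC", "MCC"]
    assert "spontaneous_with_spatial" in report
    assert "mcc_by_group_and_arm" in report


def test_subgroup_matrices_use_only_their_folds():
    """Subgroup means recomputed by brute force from the long table match
    the subgroup report matrices."""
    results = {"with_spatial": {"RF": [
        _fold("m0", "spontaneous", tp=20, tn=20, fp=1, fn=1),
        _fold("m1", "inflammation", tp=5, tn=5, fp=5, fn=5)]}}
    report = build_report(results)
    frame = fold_frame(results)
    spont = frame[(frame.model_group == "spontaneous") & (frame.metric == "MCC")]
    assert report["spontaneous_with_spatial"].loc["RF", "MCC"] == \
        pytest.approx(spont.value.mean())
    inflam = frame[(frame.model_group == "inflammation") & (frame.metric == "MCC")]
    assert report["inflammation_with_spatial"].loc["RF", "MCC"] == \
        pytest.approx(inflam.value.mean())


def test_report_round_trips_through_csv(tmp_path):
    results = {"with_spatial": {"RF": [_fold(), _fold("m1")]}}
    report = build_report(results, groups=False)
    for name, mat in report.items():
        path = tmp_path / f"{name}.csv"
        mat.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(back.to_numpy(), mat.to_numpy())


# ---------------------------------------------------------------------------
# ANOVA


def _balanced_table(effects, reps=4, noise=0.0, seed=0):
    """2x2x2 balanced design with additive factor effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for clf, metric, arm in itertools.product(("RF", "AB"), ("ACC", "MCC"),
                                              ("with_spatial", "without_spatial")):
        base = (effects.get(clf, 0.0) + effects.get(metric, 0.0)
                + effects.get(arm, 0.0))
        for _ in range(reps):
            rows.append({"classifier": clf, "metric": metric, "arm": arm,
                         "value": base + rng.normal(0, noise)})
    return pd.DataFrame(rows)


def test_constant_values_explain_nothing():
    df = _balanced_table({}, noise=0.0)
    res = anova_compare(df)
    for factor in res.factors.values():
        assert factor["partial_eta_sq"] == 0.0
        assert factor["p"] == pytest.approx(1.0)


def test_partial_eta_squared_matches_sums_of_squares_oracle():
    """On a balanced 2x2x2 design the partial eta squared of each factor
    equals the hand-computed SS_effect / (SS_effect + SS_residual)."""
    df = _balanced_table({"MCC": -0.4, "AB": 0.1, "with_spatial": 0.05},
                         noise=0.02, seed=1)
    res = anova_compare(df)
    grand = df.value.mean()
    n = len(df)
    ss_res = None
    # residual SS: deviations from the additive cell model fitted by means
    fitted = df.copy()
    for col in ("classifier", "metric", "arm"):
        means = df.groupby(col).value.mean() - grand
        fitted[col + "_eff"] = fitted[col].map(means)
    fitted["pred"] = grand + fitted[["classifier_eff", "metric_eff", "arm_eff"]].sum(axis=1)
    ss_res = float(((fitted.value - fitted.pred) ** 2).sum())
    for factor, col in (("classifier", "classifier"), ("metric", "metric"),
                        ("spatial_features", "arm")):
        means = df.groupby(col).value.mean()
        counts = df.groupby(col).value.count()
        ss_effect = float((counts * (means - grand) ** 2).sum())
        expected = ss_effect / (ss_effect + ss_res)
        assert res.factors[factor]["partial_eta_sq"] == pytest.approx(
            expected, rel=1e-6)


def test_metric_factor_dominates_on_separated_ranges():
    """When one metric lives on a different scale, the metric factor
    explains the largest share of variance."""
    df = _balanced_table({"MCC": -0.5, "AB": 0.05, "with_spatial": 0.02},
                         noise=0.02, seed=2)
    res = anova_compare(df)
    etas = {k: v["partial_eta_sq"] for k, v in res.factors.items()}
    assert max(etas, key=etas.get) == "metric"
    assert res.factors["metric"]["p"] < 0.0005


def test_single_level_factor_skipped():
    df = _balanced_table({"MCC": -0.5}, noise=0.05)
    df = df[df.arm == "with_spatial"]
    res = anova_compare(df)
    assert "spatial_features" not in res.factors
    assert "metric" in res.factors
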