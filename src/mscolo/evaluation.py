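"""Classifier evaluation: ACC, ACC2, AUC, MCC, report matrices and ANOVA.

Per-fold confusion counts yield

    ACC  = (TP + TN) / (TP + TN + FP + FN)
    Sen  = TP / (TP + FN),   Spe = TN / (TN + FP)
    ACC2 = (Sen + Spe) / 2                       (balanced accuracy)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any marginal is empty (standard convention; it
keeps fold means defined).  AUC is the probability that a random positive
pixel scores above a random negative one (Mann-Whitney statistic; ties
count one half); it is computed per held-out animal and averaged over
folds, mirroring how the other metrics are aggregated.  The final numbers
are unweighted means over all leave-one-out folds.

The with/without-spatial-features comparison is a three-factor fixed-effects
ANOVA over {classifier, metric, spatial features} on per-fold metric
values, with type-II sums of squares and partial eta squared
SS_effect / (SS_effect + SS_residual) per factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.metrics import roc_auc_score

from .types import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts", "MetricSet", "AnovaResult",
    "metrics_from_counts", "auc_from_scores", "fold_metrics",
    "aggregate_folds", "fold_frame", "build_report", "report_from_frame",
    "anova_compare",
]

METRIC_ORDER = ["ACC", "ACC2", "AUC", "MCC"]
CLASSIFIER_ORDER = ["RF", "RB", "SVM_lin", "SVM_gauss", "AB"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    acc: float
    acc2: float
    sen: float
    spe: float
    mcc: float
    auc: float = math.nan


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """ACC, Sen/Spe, ACC2 and MCC from one confusion table (AUC excluded).

    Empty sensitivity/specificity denominators yield 0 for that rate; an
    MCC denominator with any empty marginal yields MCC = 0.
    """
    if c.total == 0:
        raise ParameterError("confusion counts are all zero")
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    acc = (tp + tn) / c.total
    sen = tp / (tp + fn) if tp + fn > 0 else 0.0
    spe = tn / (tn + fp) if tn + fp > 0 else 0.0
    acc2 = (sen + spe) / 2.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricSet(acc=acc, acc2=acc2, sen=sen, spe=spe, mcc=mcc)


def auc_from_scores(scores, labels) -> float:
    """Rank AUC (Mann-Whitney normalization; ties count one half).

    With a single class present the AUC is undefined and reported as NaN.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        logger.warning("AUC undefined for a single-class fold; reporting NaN")
        return math.nan
    return float(roc_auc_score(labels, scores))


def fold_metrics(fold) -> MetricSet:
    """Full metric set (including AUC) of one FoldResult."""
    ms = metrics_from_counts(ConfusionCounts(fold.tp, fold.tn, fold.fp, fold.fn))
    ms.auc = auc_from_scores(fold.scores, fold.y_true)
    return ms


def aggregate_folds(fold_results) -> MetricSet:
    """Unweighted mean of per-fold metrics over all leave-one-out folds."""
    if not fold_results:
        raise ParameterError("no folds to aggregate")
    sets = [fold_metrics(f) for f in fold_results]

    def mean(attr):
        vals = [getattr(s, attr) for s in sets]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    return MetricSet(acc=mean("acc"), acc2=mean("acc2"), sen=mean("sen"),
                     spe=mean("spe"), mcc=mean("mcc"), auc=mean("auc"))


# ---------------------------------------------------------------------------
# report matrices


def fold_frame(results_by_arm: dict) -> pd.DataFrame:
    """Long-format per-fold metric table.

    *results_by_arm* maps an arm label ('with_spatial' / 'without_spatial')
    to a ``{classifier: [FoldResult, ...]}`` mapping as returned by
    :func:`mscolo.model.loo_crossvalidate`.
    """
    rows = []
    for arm, by_clf in results_by_arm.items():
        for clf, folds in by_clf.items():
            for f in folds:
                ms = fold_metrics(f)
                for metric, value in (("ACC", ms.acc), ("ACC2", ms.acc2),
                                      ("AUC", ms.auc), ("MCC", ms.mcc)):
                    rows.append({"arm": arm, "classifier": clf,
                                 "animal_id": f.animal_id,
                                 "model_group": f.model_group,
                                 "metric": metric, "value": value})
    return pd.DataFrame(rows)


def _matrix(frame: pd.DataFrame) -> pd.DataFrame:
    mat = (frame.groupby(["classifier", "metric"])["value"].mean()
           .unstack("metric"))
    order = [c for c in CLASSIFIER_ORDER if c in mat.index]
    cols = [m for m in METRIC_ORDER if m in mat.columns]
    return mat.loc[order, cols]


def build_report(results_by_arm: dict, groups: bool = True) -> dict[str, pd.DataFrame]:
    """Classifier x metric report matrices from raw fold results.

    Produces one 5x4 matrix per feature arm over all animals, one per
    (arm, tumour-model subgroup), and an MCC table indexed by classifier
    with (arm x subgroup) columns.  Arms missing from the input yield a
    partial report with a warning.
    """
    return report_from_frame(fold_frame(results_by_arm), groups=groups)


def report_from_frame(frame: pd.DataFrame, groups: bool = True) -> dict[str, pd.DataFrame]:
    """Same report matrices, built from the long-format per-fold table."""
    if frame.empty:
        raise ParameterError("no fold results")
    report: dict[str, pd.DataFrame] = {}
    for arm in ("without_spatial", "with_spatial"):
        sub = frame[frame["arm"] == arm]
        if sub.empty:
            logger.warning("arm %s missing; report is partial", arm)
            continue
        report[f"all_{arm}"] = _matrix(sub)
    if groups:
        for arm in sorted(frame["arm"].unique()):
            for grp in sorted(frame["model_group"].unique()):
                sub = frame[(frame["arm"] == arm) & (frame["model_group"] == grp)]
                if not sub.empty:
                    report[f"{grp}_{arm}"] = _matrix(sub)
        mcc = frame[frame["metric"] == "MCC"]
        if not mcc.empty:
            tab = (mcc.groupby(["classifier", "model_group", "arm"])["value"]
                   .mean().unstack(["model_group", "arm"]))
            order = [c for c in CLASSIFIER_ORDER if c in tab.index]
            report["mcc_by_group_and_arm"] = tab.loc[order]
    return report


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaResult:
    """Main-effect F, p and partial eta squared per factor."""

    factors: dict[str, dict[str, float]]


_FACTORS = {"classifier": "C(classifier)", "metric": "C(metric)",
            "spatial_features": "C(arm)"}


def anova_compare(metric_table: pd.DataFrame) -> AnovaResult:
    """Threefold fixed-effects ANOVA over classifier, metric and spatial arm.

    *metric_table* is the long-format frame from :func:`fold_frame` (columns
    ``value``, ``classifier``, ``metric``, ``arm``).  Factors with a single
    level are skipped.  Type-II sums of squares; partial eta squared is
    SS_effect / (SS_effect + SS_residual).
    """
    df = metric_table.dropna(subset=["value"]).copy()
    if df.empty:
        raise ParameterError("empty metric table")
    terms = {}
    for factor, term in _FACTORS.items():
        col = {"classifier": "classifier", "metric": "metric",
               "spatial_features": "arm"}[factor]
        if df[col].nunique() > 1:
            terms[factor] = term
        else:
            logger.warning("factor %s has a single level; skipped", factor)
    if not terms:
        raise ParameterError("no factor has more than one level")
    if float(df["value"].var()) < 1e-20:
        # constant response: nothing to explain
        return AnovaResult(factors={
            f: {"F": 0.0, "p": 1.0, "partial_eta_sq": 0.0} for f in terms})
    formula = "value ~ " + " + ".join(terms.values())
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    factors = {}
    for factor, term in terms.items():
        ss = float(table.loc[term, "sum_sq"])
        factors[factor] = {
            "F": float(table.loc[term, "F"]),
            "p": float(table.loc[term, "PR(>F)"]),
            "partial_eta_sq": ss / (ss + ss_resid) if ss + ss_resid > 0 else 0.0,
        }
    return AnovaResult(factors=factors)
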