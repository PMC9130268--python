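"""Feature reduction, the five classifiers, and leave-one-animal-out CV.

PCA retains the minimal leading-component set accounting for 99% of the
training variance.  Classifiers follow the study's hyperparameters:

* RF — random forest, 400 trees, minimal leaf size 3;
* RB — RobustBoost, 100 stumps, error goal 0.2;
* AB — AdaBoost, 400 stumps, learning rate 0.1;
* SVM_lin / SVM_gauss — soft-margin SVMs with feature standardization,
  automatic kernel scale and an outlier fraction of 0.05 (mapped to the
  nu-SVM budget of margin violations).

Training uses a uniformly random 1% row subsample, drawn after feature
generation and reduction; the held-out animal is always evaluated in full.
PCA is refit inside every fold by default so that no test-animal pixel can
influence the projection (``pca_scope='global'`` reproduces the laxer
single-fit reading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, NuSVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable
from .robustboost import RobustBoostClassifier
from .types import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel", "ClassifierSpec", "FoldResult", "default_classifier_specs",
    "fit_pca", "subsample_training", "train", "predict", "loo_crossvalidate",
]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Fitted PCA retaining >= ``variance_target`` cumulative variance."""

    components: np.ndarray          # (n_components, n_features)
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


def fit_pca(train_table: FeatureTable | np.ndarray,
            variance_target: float = 0.99) -> PCAModel:
    """Fit PCA on training rows, keeping the minimal component set whose
    cumulative explained variance reaches *variance_target*."""
    X = train_table.X if isinstance(train_table, FeatureTable) else np.asarray(train_table)
    if X.shape[0] < 2:
        raise ParameterError("PCA needs at least 2 rows")
    if not 0 < variance_target <= 1:
        raise ParameterError("variance_target must lie in (0, 1]")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    ratios = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    # minimal k with cumvar >= target; rank-deficient input saturates below
    # 1.0 only by float error, so fall back to all non-degenerate components
    reached = np.nonzero(cumulative >= variance_target - 1e-12)[0]
    k = int(reached[0]) + 1 if len(reached) else len(ratios)
    k = max(k, 1)
    return PCAModel(components=pca.components_[:k].copy(),
                    mean=pca.mean_.copy(),
                    explained_variance_ratio=ratios[:k].copy(),
                    n_components=k)


# ---------------------------------------------------------------------------
# training subsample


def subsample_training(table: FeatureTable, fraction: float = 0.01,
                       seed: int | np.random.SeedSequence = 0) -> FeatureTable:
    """Uniform random row subset (without replacement) of the training table.

    If the draw misses a class it is redrawn once (logged); if the redraw
    also misses, one random row of the missing class is swapped in (logged).
    """
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must lie in (0, 1]")
    n = table.n_rows
    n_keep = int(round(fraction * n))
    if n_keep < 2:
        raise ParameterError(f"fraction {fraction} of {n} rows leaves fewer than 2")
    if n_keep == n:
        return table
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_keep, replace=False)
    if len(np.unique(table.y[idx])) < 2:
        logger.warning("training subsample single-class; redrawing once")
        idx = rng.choice(n, size=n_keep, replace=False)
    if len(np.unique(table.y[idx])) < 2:
        present = table.y[idx[0]]
        missing_rows = np.nonzero(table.y != present)[0]
        if len(missing_rows) == 0:
            raise ParameterError("training table contains a single class")
        logger.warning("redraw still single-class; injecting one row of the missing class")
        idx[0] = rng.choice(missing_rows)
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return table.rows(mask)


# ---------------------------------------------------------------------------
# classifiers


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the five classifier kinds with its hyperparameters."""

    kind: str  # RF | RB | AB | SVM_lin | SVM_gauss
    params: tuple = ()

    def build(self, random_state: int):
        p = dict(self.params)
        if self.kind == "RF":
            return RandomForestClassifier(
                n_estimators=p.get("n_estimators", 400),
                min_samples_leaf=p.get("min_samples_leaf", 3),
                random_state=random_state, n_jobs=1)
        if self.kind == "AB":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=p.get("n_estimators", 400),
                learning_rate=p.get("learning_rate", 0.1),
                random_state=random_state)
        if self.kind == "RB":
            return RobustBoostClassifier(
                n_estimators=p.get("n_estimators", 100),
                error_goal=p.get("error_goal", 0.2),
                random_state=random_state)
        if self.kind in ("SVM_lin", "SVM_gauss"):
            kernel = "linear" if self.kind == "SVM_lin" else "rbf"
            return make_pipeline(
                StandardScaler(),
                NuSVC(nu=p.get("outlier_fraction", 0.05), kernel=kernel,
                      gamma="scale", random_state=random_state))
        raise ParameterError(f"unknown classifier kind {self.kind!r}")


def default_classifier_specs() -> list[ClassifierSpec]:
    """The five classifiers with the study hyperparameters."""
    return [ClassifierSpec("RF"), ClassifierSpec("RB"), ClassifierSpec("AB"),
            ClassifierSpec("SVM_lin"), ClassifierSpec("SVM_gauss")]


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object


def train(spec: ClassifierSpec, table: FeatureTable,
          random_state: int = 0) -> TrainedModel:
    """Fit one classifier on a (projected, subsampled) training table."""
    if len(np.unique(table.y)) < 2:
        raise ParameterError("training table contains a single class")
    est = spec.build(random_state)
    try:
        est.fit(table.X, table.y)
    except ValueError as exc:
        if spec.kind in ("SVM_lin", "SVM_gauss"):
            # nu infeasible for extreme class imbalance: fall back to C-SVM
            logger.warning("%s: nu=0.05 infeasible (%s); using C-SVM", spec.kind, exc)
            kernel = "linear" if spec.kind == "SVM_lin" else "rbf"
            est = make_pipeline(StandardScaler(),
                                SVC(kernel=kernel, gamma="scale",
                                    random_state=random_state))
            est.fit(table.X, table.y)
        else:
            raise
    return TrainedModel(spec=spec, estimator=est)


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous score (for AUC) and hard 0/1 label per row."""
    est = model.estimator
    if hasattr(est, "decision_function"):
        scores = np.asarray(est.decision_function(X), dtype=float)
    else:
        scores = np.asarray(est.predict_proba(X)[:, 1], dtype=float)
    labels = np.asarray(est.predict(X)).astype(int)
    return scores, labels


# ---------------------------------------------------------------------------
# leave-one-animal-out cross-validation


@dataclass
class FoldResult:
    """Outcome of one leave-one-animal-out fold for one classifier."""

    animal_id: str
    model_group: str
    classifier: str
    tp: int
    tn: int
    fp: int
    fn: int
    scores: np.ndarray
    labels: np.ndarray
    y_true: np.ndarray
    train_row_indices: np.ndarray
    pca_mean: np.ndarray
    pca_components: np.ndarray
    n_pca_components: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _fold_seed(seed: int, fold: int, which: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(fold, which))


def loo_crossvalidate(cohort_features: FeatureTable,
                      specs: list[ClassifierSpec] | None = None,
                      seed: int = 0, variance_target: float = 0.99,
                      subsample_fraction: float = 0.01,
                      pca_scope: str = "fold") -> dict[str, list["FoldResult"]]:
    """One fold per animal: PCA fit on the training animals, both sides
    projected, 1% of training rows subsampled, classifiers trained, and the
    held-out animal predicted in full."""
    specs = specs or default_classifier_specs()
    animals = cohort_features.animals()
    if len(animals) < 2:
        raise ParameterError("need at least 2 animals for leave-one-out")
    if pca_scope not in ("fold", "global"):
        raise ParameterError("pca_scope must be 'fold' or 'global'")
    animal_col = cohort_features.index["animal_id"].to_numpy()
    group_by_animal = dict(zip(animal_col, cohort_features.index["model_group"]))
    global_pca = fit_pca(cohort_features, variance_target) if pca_scope == "global" else None

    results: dict[str, list[FoldResult]] = {s.kind: [] for s in specs}
    for fold, animal in enumerate(animals):
        test_mask = animal_col == animal
        train_mask = ~test_mask
        test_table = cohort_features.rows(test_mask)
        if test_table.n_rows == 0:
            logger.warning("animal %s has no valid labelled pixels; fold skipped", animal)
            continue
        train_table = cohort_features.rows(train_mask)
        pca = global_pca or fit_pca(train_table, variance_target)
        train_proj = FeatureTable(
            pca.transform(train_table.X), train_table.y,
            _component_columns(pca.n_components), train_table.index)
        sub = subsample_training(train_proj, subsample_fraction,
                                 _fold_seed(seed, fold, 0))
        test_X = pca.transform(test_table.X)
        train_row_ids = np.nonzero(train_mask)[0]
        for j, spec in enumerate(specs):
            rs = int(_fold_seed(seed, fold, j + 1).generate_state(1)[0] % (2 ** 31 - 1))
            model = train(spec, sub, random_state=rs)
            scores, labels = predict(model, test_X)
            y = test_table.y
            results[spec.kind].append(FoldResult(
                animal_id=animal,
                model_group=group_by_animal[animal],
                classifier=spec.kind,
                tp=int(np.sum((labels == 1) & (y == 1))),
                tn=int(np.sum((labels == 0) & (y == 0))),
                fp=int(np.sum((labels == 1) & (y == 0))),
                fn=int(np.sum((labels == 0) & (y == 1))),
                scores=scores, labels=labels, y_true=y.copy(),
                train_row_indices=train_row_ids,
                pca_mean=pca.mean.copy(),
                pca_components=pca.components.copy(),
                n_pca_components=pca.n_components))
    return results


def _component_columns(k: int):
    import pandas as pd

    return pd.DataFrame({"family": ["pca"] * k, "band": [-1] * k,
                         "l": [-1] * k, "p": [-1] * k})
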