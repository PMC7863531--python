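"""Classifier training, tuning, and evaluation statistics for LOS prediction.

Four classifiers are compared — multinomial logistic regression, a
single-hidden-layer feed-forward neural network, random forest, and
gradient boosting — each tuned by exhaustive grid search under k-fold
cross-validation (macro-F1 selection).  Evaluation is per LOS class:
one-vs-rest precision, recall and F1 from the 4x4 confusion matrix, their
unweighted macro averages, and the best-vs-worst performance gap
(pm_best − pm_worst) / pm_best.

Entropy and information gain — the split criterion underlying the tree
ensembles — are exposed as audited utilities; tree induction itself is
delegated to scikit-learn.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .preprocessing import LOS_CLASSES, FeatureManifest

ALGORITHMS = ("logistic_regression", "ann", "random_forest", "gradient_boosting")

# Grid ranges used for hyperparameter search.
DEFAULT_GRID_RANGES = {
    "n_trees": list(range(100, 1001, 100)),
    "learning_rates": [0.01, 0.05, 0.10],
    "min_node_obs": list(range(2, 11, 1)),
    "split_candidates": list(range(2, 11, 2)),
    "hidden_nodes": list(range(1, 9)),
}

ANN_MAX_EPOCHS = 500  # feed-forward backprop budget


@dataclass
class TuningGrid:
    """Hyperparameter grid for one algorithm.

    Defaults: trees 100–1000 step 100; learning rate {0.01, 0.05, 0.10};
    minimum terminal-node observations 2–10 step 1; split candidates
    (features tried per split) 2–10 step 2; ANN hidden nodes 1–8.
    """

    algorithm: str
    n_trees: Sequence[int] = ()
    learning_rates: Sequence[float] = ()
    min_node_obs: Sequence[int] = ()
    split_candidates: Sequence[int] = ()
    hidden_nodes: Sequence[int] = ()

    @classmethod
    def default(cls, algorithm: str) -> "TuningGrid":
        r = DEFAULT_GRID_RANGES
        if algorithm == "logistic_regression":
            return cls(algorithm)  # no tunable parameters
        if algorithm == "ann":
            return cls(algorithm, hidden_nodes=r["hidden_nodes"],
                       learning_rates=r["learning_rates"])
        if algorithm == "random_forest":
            return cls(algorithm, n_trees=r["n_trees"],
                       min_node_obs=r["min_node_obs"],
                       split_candidates=r["split_candidates"])
        if algorithm == "gradient_boosting":
            return cls(algorithm, n_trees=r["n_trees"],
                       learning_rates=r["learning_rates"],
                       min_node_obs=r["min_node_obs"],
                       split_candidates=r["split_candidates"])
        raise ValueError(f"unknown algorithm {algorithm!r}")

    def points(self) -> list[dict]:
        """Grid points ordered smallest-model-first (the tie-break order)."""
        axes: list[tuple[str, Sequence]] = []
        if self.algorithm == "ann":
            axes = [("hidden_nodes", self.hidden_nodes or [4]),
                    ("learning_rates", self.learning_rates or [0.01])]
        elif self.algorithm == "random_forest":
            axes = [("n_trees", self.n_trees or [100]),
                    ("min_node_obs", self.min_node_obs or [2]),
                    ("split_candidates", self.split_candidates or [2])]
        elif self.algorithm == "gradient_boosting":
            axes = [("n_trees", self.n_trees or [100]),
                    ("learning_rates", self.learning_rates or [0.1]),
                    ("min_node_obs", self.min_node_obs or [2]),
                    ("split_candidates", self.split_candidates or [2])]
        elif self.algorithm == "logistic_regression":
            return [{}]
        names = [n for n, _ in axes]
        return [dict(zip(names, combo))
                for combo in itertools.product(*(sorted(v) for _, v in axes))]


def _make_estimator(algorithm: str, params: Mapping, n_features: int, seed: int):
    if algorithm == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if algorithm == "ann":
        return MLPClassifier(
            hidden_layer_sizes=(int(params.get("hidden_nodes", 4)),),
            activation="logistic",
            learning_rate_init=float(params.get("learning_rates", 0.01)),
            max_iter=ANN_MAX_EPOCHS,
            random_state=seed,
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_trees", 100)),
            min_samples_leaf=int(params.get("min_node_obs", 2)),
            max_features=min(int(params.get("split_candidates", 2)), n_features),
            random_state=seed,
        )
    if algorithm == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=int(params.get("n_trees", 100)),
            learning_rate=float(params.get("learning_rates", 0.1)),
            min_samples_leaf=int(params.get("min_node_obs", 2)),
            max_features=min(int(params.get("split_candidates", 2)), n_features),
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# Splitting and training
# ---------------------------------------------------------------------------

def split_train_test(records: Sequence, test_fraction: float = 0.20,
                     seed: int = 0) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test split (default 80/20)."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction {test_fraction} outside (0, 1)")
    if len(records) < 10:
        raise ValueError(f"too few records to split: {len(records)}")
    train, test = train_test_split(list(records), test_size=test_fraction,
                                   random_state=seed, shuffle=True)
    return train, test


@dataclass
class FittedModel:
    algorithm: str
    estimator: object
    best_params: dict
    cv_macro_f1: float | None
    training_time_s: float
    manifest: FeatureManifest | None = None


def _cv_macro_f1(est, X, y, cv_folds, seed) -> float:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        m = clone(est)
        m.fit(X[tr], y[tr])
        pred = m.predict(X[te])
        cm = ConfusionMatrix.from_predictions(y[te], pred)
        scores.append(macro_average([score(cm, c)[2] for c in LOS_CLASSES]))
    return float(np.mean(scores))


def tune_and_train(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: TuningGrid | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    manifest: FeatureManifest | None = None,
) -> FittedModel:
    """Exhaustive grid search with k-fold CV (macro-F1 selection), then a
    final fit on the full training data.

    A single-point grid skips cross-validation entirely.  Exact score ties
    go to the earlier grid point — grids are ordered smallest-model-first,
    so ties favour the smaller model.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training target: a single LOS class; "
                         "cannot fit a classifier")
    if grid is None:
        grid = TuningGrid.default(algorithm)
    if grid.algorithm != algorithm:
        raise ValueError("grid/algorithm mismatch")

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    points = grid.points()

    t0 = time.perf_counter()
    best_params, best_score = points[0], None
    if len(points) > 1:
        best_score = -np.inf
        for params in points:
            est = _make_estimator(algorithm, params, X.shape[1], seed)
            s = _cv_macro_f1(est, X, y, cv_folds, seed)
            if s > best_score:  # strict: ties keep the earlier (smaller) point
                best_score, best_params = s, params
    est = _make_estimator(algorithm, best_params, X.shape[1], seed)
    est.fit(X, y)
    elapsed = time.perf_counter() - t0
    return FittedModel(algorithm, est, dict(best_params),
                       None if best_score in (None, -np.inf) else float(best_score),
                       elapsed, manifest)


# ---------------------------------------------------------------------------
# Linear predictors (multinomial logistic regression)
# ---------------------------------------------------------------------------

@dataclass
class LinearPredictorModel:
    """Per-class linear predictors f(class, i) = beta_0,class + sum_v beta_v,class x_v."""

    classes: list[str]
    coefficients: np.ndarray  # (n_classes, n_features)
    intercepts: np.ndarray    # (n_classes,)

    @classmethod
    def from_fitted(cls, fitted: FittedModel) -> "LinearPredictorModel":
        if fitted.algorithm != "logistic_regression":
            raise ValueError("linear predictors are defined for logistic regression")
        est = fitted.estimator
        return cls(classes=list(est.classes_),
                   coefficients=np.asarray(est.coef_, dtype=float),
                   intercepts=np.asarray(est.intercept_, dtype=float))


def linear_predictor(model: LinearPredictorModel, x: np.ndarray, los_class: str) -> float:
    """Score beta_0,class + beta_class . x for one class."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.coefficients.shape[1],):
        raise ValueError(
            f"feature vector length {x.shape} does not match model "
            f"({model.coefficients.shape[1]} features)")
    k = model.classes.index(los_class)
    return float(model.intercepts[k] + model.coefficients[k] @ x)


def class_probabilities(model: LinearPredictorModel, x: np.ndarray) -> dict[str, float]:
    """Softmax over the per-class linear predictor scores."""
    scores = np.array([linear_predictor(model, x, c) for c in model.classes])
    scores -= scores.max()
    p = np.exp(scores)
    p /= p.sum()
    return dict(zip(model.classes, p))


# ---------------------------------------------------------------------------
# Entropy and information gain (tree split criterion)
# ---------------------------------------------------------------------------

def entropy(class_proportions: Sequence[float]) -> float:
    """Shannon entropy in bits, -sum p_i log2 p_i, with 0 log 0 := 0."""
    p = np.asarray(class_proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportion")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def information_gain(parent_counts: Sequence[float],
                     children_counts: Sequence[Sequence[float]]) -> float:
    """Entropy(parent) − weighted average entropy(children), in bits.

    The children must partition the parent counts exactly.  The result is
    mathematically non-negative; tiny negative floating residue is
    clamped to 0.
    """
    parent = np.asarray(parent_counts, dtype=float)
    children = [np.asarray(c, dtype=float) for c in children_counts]
    if not np.allclose(sum(children), parent):
        raise ValueError("children counts do not partition the parent counts")
    n = parent.sum()
    if n == 0:
        raise ValueError("empty parent")
    h_parent = entropy(parent / n)
    h_children = 0.0
    for c in children:
        nc = c.sum()
        if nc > 0:
            h_children += (nc / n) * entropy(c / nc)
    return max(0.0, h_parent - h_children)


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """4x4 counts indexed (actual LOS class, predicted LOS class)."""

    counts: np.ndarray
    classes: tuple[str, ...] = LOS_CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("negative count in confusion matrix")

    @classmethod
    def from_predictions(cls, actual: Sequence[str], predicted: Sequence[str],
                         classes: Sequence[str] = LOS_CLASSES) -> "ConfusionMatrix":
        m = _sk_confusion(list(actual), list(predicted), labels=list(classes))
        return cls(counts=m, classes=tuple(classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def score(confusion: ConfusionMatrix, los_class: str) -> tuple[float, float, float]:
    """One-vs-rest (precision, recall, F1) for one LOS class.

    precision = TP/(TP+FP); recall = TP/(TP+FN); F1 = 2TP/(2TP+FP+FN).
    A zero denominator yields 0.
    """
    k = confusion.classes.index(los_class)
    m = confusion.counts
    tp = m[k, k]
    fp = m[:, k].sum() - tp
    fn = m[k, :].sum() - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    return float(precision), float(recall), float(f1)


def macro_average(per_class_values: Sequence[float]) -> float:
    """Unweighted arithmetic mean over the four LOS classes."""
    if len(per_class_values) != len(LOS_CLASSES):
        raise ValueError(f"expected {len(LOS_CLASSES)} per-class values, "
                         f"got {len(per_class_values)}")
    return float(np.mean(per_class_values))


def performance_gap(pm_best: float, pm_worst: float, tol: float = 1e-9) -> float:
    """(pm_best − pm_worst) / pm_best, the best-vs-worst relative gap."""
    if pm_best <= 0:
        raise ValueError("pm_best must be positive")
    if pm_worst > pm_best + tol:
        raise ValueError(f"pm_worst {pm_worst} exceeds pm_best {pm_best}")
    return float((pm_best - pm_worst) / pm_best)


@dataclass
class EvaluationReport:
    algorithm: str
    per_class: dict  # class -> {"precision": .., "recall": .., "f1": ..}
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: ConfusionMatrix | None = None
    training_time_s: float | None = None
    hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "per_class": self.per_class,
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall, "f1": self.macro_f1},
            "confusion": None if self.confusion is None
            else self.confusion.counts.tolist(),
            "training_time_s": self.training_time_s,
            "hyperparameters": self.hyperparameters,
        }


def evaluate(fitted: FittedModel, X_test: np.ndarray, y_test: np.ndarray,
             ) -> EvaluationReport:
    pred = fitted.estimator.predict(np.asarray(X_test, dtype=float))
    cm = ConfusionMatrix.from_predictions(y_test, pred)
    return report_from_confusion(cm, fitted.algorithm,
                                 training_time_s=fitted.training_time_s,
                                 hyperparameters=fitted.best_params)


def report_from_confusion(cm: ConfusionMatrix, algorithm: str,
                          training_time_s: float | None = None,
                          hyperparameters: dict | None = None) -> EvaluationReport:
    per_class = {}
    for c in cm.classes:
        p, r, f1 = score(cm, c)
        per_class[c] = {"precision": p, "recall": r, "f1": f1}
    return EvaluationReport(
        algorithm=algorithm,
        per_class=per_class,
        macro_precision=macro_average([per_class[c]["precision"] for c in cm.classes]),
        macro_recall=macro_average([per_class[c]["recall"] for c in cm.classes]),
        macro_f1=macro_average([per_class[c]["f1"] for c in cm.classes]),
        confusion=cm,
        training_time_s=training_time_s,
        hyperparameters=dict(hyperparameters or {}),
    )


def results_table(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Consolidated per-class results: rows = class x metric, columns =
    algorithm, plus an Average row per metric."""
    rows = []
    for metric in ("precision", "recall", "f1"):
        for c in LOS_CLASSES:
            rows.append({"los_class": c, "metric": metric,
                         **{rep.algorithm: rep.per_class[c][metric]
                            for rep in reports}})
        rows.append({"los_class": "average", "metric": metric,
                     **{rep.algorithm: getattr(rep, f"macro_{metric}")
                        for rep in reports}})
    return pd.DataFrame(rows)


def compute_gaps(reports: Sequence[EvaluationReport]) -> dict[str, float]:
    """Best-vs-worst macro gap per metric across algorithms (fractions)."""
    gaps = {}
    for metric in ("precision", "recall", "f1"):
        vals = [getattr(rep, f"macro_{metric}") for rep in reports]
        gaps[metric] = performance_gap(max(vals), min(vals))
    return gaps


# ---------------------------------------------------------------------------
# Replay: recompute averages/gaps from a per-class metric table
# ---------------------------------------------------------------------------

def load_reference_metrics(path: str | Path | None = None) -> pd.DataFrame:
    """Per-class benchmark table (long form: algorithm, metric, one column
    per LOS class).  The bundled default is the published four-algorithm
    benchmark on the multi-state shelter dataset."""
    if path is None:
        with resources.files("shelterops.data").joinpath(
                "reference_metrics.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def replay_reports(table: pd.DataFrame) -> list[EvaluationReport]:
    """Rebuild evaluation reports from a per-class metric table (no
    training): macro averages and gaps are recomputed from the per-class
    values exactly as in a live run."""
    required = {"algorithm", "metric", *LOS_CLASSES}
    if not required.issubset(table.columns):
        raise ValueError(f"metric table needs columns {sorted(required)}")
    reports = []
    for algo, sub in table.groupby("algorithm", sort=False):
        per_class: dict[str, dict[str, float]] = {c: {} for c in LOS_CLASSES}
        for row in sub.itertuples(index=False):
            for c in LOS_CLASSES:
                per_class[c][row.metric] = float(getattr(row, c))
        reports.append(EvaluationReport(
            algorithm=algo,
            per_class=per_class,
            macro_precision=macro_average(
                [per_class[c]["precision"] for c in LOS_CLASSES]),
            macro_recall=macro_average(
                [per_class[c]["recall"] for c in LOS_CLASSES]),
            macro_f1=macro_average([per_class[c]["f1"] for c in LOS_CLASSES]),
        ))
    return reports


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------

@dataclass
class FeatureImportanceTable:
    entries: list[tuple[str, float]]  # sorted non-increasing

    def top_k(self, k: int) -> list[tuple[str, float]]:
        return self.entries[:k]

    def names(self) -> list[str]:
        return [n for n, _ in self.entries]


def _macro_f1_of(est, X, y) -> float:
    cm = ConfusionMatrix.from_predictions(y, est.predict(X))
    return macro_average([score(cm, c)[2] for c in LOS_CLASSES])


def feature_importance(
    fitted: FittedModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    method: str = "permutation",
    k: int = 3,
    repeats: int = 10,
    seed: int = 0,
) -> FeatureImportanceTable:
    """Rank encoded features by importance.

    ``permutation`` (any algorithm): mean macro-F1 drop on the test set
    after shuffling one indicator column, over ``repeats`` shuffles.
    ``native``: |standardized coefficient| averaged over classes for
    logistic regression, impurity importance for the tree ensembles;
    undefined for the ANN.
    """
    if method not in ("permutation", "native"):
        raise ValueError(f"unknown importance method {method!r}")
    if fitted.manifest is None:
        raise ValueError("fitted model carries no feature manifest")
    names = fitted.manifest.names
    X = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test, dtype=object)

    if method == "native":
        est = fitted.estimator
        if fitted.algorithm == "logistic_regression":
            stds = X.std(axis=0)
            scores = (np.abs(est.coef_) * stds).mean(axis=0)
        elif fitted.algorithm in ("random_forest", "gradient_boosting"):
            scores = np.asarray(est.feature_importances_, dtype=float)
        else:
            raise ValueError(
                "native importance is undefined for the ANN; use permutation")
    else:
        rng = np.random.default_rng(seed)
        base = _macro_f1_of(fitted.estimator, X, y)
        scores = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            drops = []
            for _ in range(repeats):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops.append(base - _macro_f1_of(fitted.estimator, Xp, y))
            scores[j] = float(np.mean(drops))

    order = np.argsort(-scores, kind="stable")
    entries = [(names[j], float(scores[j])) for j in order]
    if k is not None:
        entries = entries[:k]
    return FeatureImportanceTable(entries=entries)
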