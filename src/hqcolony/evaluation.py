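"""Metrics, cross-validated grid search and the classifier-comparison harness.

Scoring uses balanced accuracy (mean of colony sensitivity and background
specificity — the two pixel classes are heavily imbalanced), AUROC, and the
two overlap measures reported for segmentations, Jaccard and Dice
(Dice = 2J / (1 + J)).

Hyperparameter selection is an exhaustive grid with stratified 5-fold
cross-validation on the development set: for the Helstrom classifier the
grid is rescale {0.5, 1, 1.5, 2} x encoding {amplitude, stereographic} x
copies {1..4} (3-channel feature sets) or {1..5} (scalar descriptors) x
weighting {equiprobable, weighted} — 64 or 80 combinations.  Ties are
broken by the first combination in that enumeration order.  Baseline
classifiers come from scikit-learn and are tuned by the same protocol over
small conventional grids.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, PassiveAggressiveClassifier, Perceptron
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .dataset import PixelTable
from .exceptions import InvalidParameterError
from .quantum import HelstromClassifier

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "GridSearchResult",
    "confusion_counts",
    "metrics",
    "hqc_param_grid",
    "grid_search",
    "copies_increment_rerun",
    "default_roster",
    "compare_classifiers",
]

RESCALE_GRID = (0.5, 1.0, 1.5, 2.0)
ENCODING_GRID = ("amplitude", "stereographic")
WEIGHTING_GRID = ("equiprobable", "weighted")
COPIES_GRID = {"triplet": (1, 2, 3, 4), "scalar": (1, 2, 3, 4, 5)}

#: baselines without a probability-like score, excluded when the objective
#: is AUROC (15 of the 18 remain usable)
SCORELESS_BASELINES = frozenset(
    {"Nearest Centroid", "Passive Aggressive Classifier", "Perceptron"}
)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricReport:
    balanced_accuracy: float
    auroc: float
    jaccard: float
    dice: float
    counts: ConfusionCounts


def confusion_counts(labels, predictions, positive=1) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    pos = labels == positive
    pred_pos = predictions == positive
    return ConfusionCounts(
        TP=int(np.sum(pos & pred_pos)),
        FP=int(np.sum(~pos & pred_pos)),
        FN=int(np.sum(pos & ~pred_pos)),
        TN=int(np.sum(~pos & ~pred_pos)),
    )


def metrics(labels, predictions, scores=None, positive=1) -> MetricReport:
    """Balanced accuracy, AUROC, Jaccard and Dice for one evaluation.

    AUROC needs ``scores`` (probability of the positive class) and both
    classes present; otherwise it is NaN with a warning.  With a single
    class present, balanced accuracy degrades to the recall of that class
    (with a warning).
    """
    c = confusion_counts(labels, predictions, positive=positive)
    recalls = []
    if c.TP + c.FN > 0:
        recalls.append(c.TP / (c.TP + c.FN))
    if c.TN + c.FP > 0:
        recalls.append(c.TN / (c.TN + c.FP))
    if len(recalls) < 2:
        warnings.warn("only one class present; balanced accuracy degrades to its recall")
    balanced = float(np.mean(recalls)) if recalls else float("nan")

    denom = c.TP + c.FP + c.FN
    jaccard = c.TP / denom if denom > 0 else 1.0
    dice = 2 * c.TP / (2 * c.TP + c.FP + c.FN) if denom > 0 else 1.0

    labels = np.asarray(labels)
    if scores is None:
        auroc = float("nan")
    elif len(np.unique(labels)) < 2:
        warnings.warn("only one class present; AUROC is undefined")
        auroc = float("nan")
    else:
        auroc = float(roc_auc_score(labels == positive, np.asarray(scores)))
    return MetricReport(balanced, auroc, float(jaccard), float(dice), c)


def hqc_param_grid(feature_set_kind: str) -> list[dict]:
    """Exhaustive HQC grid in documented enumeration order (rescale,
    encoding, copies, weighting; each ascending).

    ``feature_set_kind`` is "triplet" (RGB / L*u*v*; copies 1-4, 64
    combinations) or "scalar" (texture descriptors; copies 1-5, 80).
    """
    if feature_set_kind not in COPIES_GRID:
        raise InvalidParameterError(
            f"feature_set_kind must be 'triplet' or 'scalar', got {feature_set_kind!r}"
        )
    return [
        {
            "rescale_factor": r,
            "encoding": e,
            "n_copies": m,
            "class_weighting": w,
        }
        for r, e, m, w in itertools.product(
            RESCALE_GRID, ENCODING_GRID, COPIES_GRID[feature_set_kind], WEIGHTING_GRID
        )
    ]


@dataclass
class GridSearchResult:
    results: pd.DataFrame
    best_params: dict
    best_score: float
    best_estimator: object
    objective: str
    test_metrics: MetricReport | None = None
    seed: int = 0
    param_grid: list = field(default_factory=list, repr=False)


def _score_fitted(est, X, y, objective: str) -> float:
    pred = est.predict(X)
    if objective == "balanced_accuracy":
        return metrics(y, pred).balanced_accuracy
    if objective == "auroc":
        scores = _positive_scores(est, X)
        if scores is None:
            raise InvalidParameterError(
                f"{type(est).__name__} exposes no probability-like score for AUROC"
            )
        return metrics(y, pred, scores=scores).auroc
    raise InvalidParameterError(f"unknown objective {objective!r}")


def _positive_scores(est, X):
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    if hasattr(est, "decision_function"):
        return est.decision_function(X)
    return None


def _as_xy(data):
    if isinstance(data, PixelTable):
        return data.X, data.y
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y)


def _cv_mean_score(estimator, params, X, y, folds, objective) -> float:
    scores = []
    for train, valid in folds:
        est = clone(estimator).set_params(**params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[train], y[train])
            scores.append(_score_fitted(est, X[valid], y[valid], objective))
    return float(np.mean(scores))


def grid_search(
    dev,
    feature_set_kind: str = "scalar",
    objective: str = "balanced_accuracy",
    seed: int = 0,
    estimator=None,
    param_grid: list | None = None,
    n_folds: int = 5,
    test=None,
) -> GridSearchResult:
    """Stratified k-fold grid search; refits the winner on the full
    development set (and scores ``test`` when given).

    The winner is the first combination, in enumeration order, attaining
    the maximal mean validation score.
    """
    X, y = _as_xy(dev)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("development data must contain both classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"cannot stratify {n_folds} folds: minority class has only {counts.min()} samples"
        )
    if estimator is None:
        estimator = HelstromClassifier(standardize=True)
    if param_grid is None:
        param_grid = hqc_param_grid(feature_set_kind)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rows = []
    for params in param_grid:
        rows.append({**params, "mean_validation_score": _cv_mean_score(
            estimator, params, X, y, folds, objective)})
    results = pd.DataFrame(rows)
    best_idx = int(np.argmax(results["mean_validation_score"].to_numpy()))
    best_params = dict(param_grid[best_idx])
    best_score = float(results["mean_validation_score"].iloc[best_idx])
    best_est = clone(estimator).set_params(**best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best_est.fit(X, y)
    out = GridSearchResult(results, best_params, best_score, best_est, objective,
                           seed=seed, param_grid=list(param_grid))
    if test is not None:
        Xt, yt = _as_xy(test)
        out.test_metrics = metrics(yt, best_est.predict(Xt),
                                   scores=_positive_scores(best_est, Xt))
    return out


def copies_increment_rerun(best: GridSearchResult, dev, test) -> dict:
    """Refit the winning HQC with one extra tensor copy, all other
    hyperparameters fixed, and report both test scores side by side."""
    X, y = _as_xy(dev)
    Xt, yt = _as_xy(test)
    base = best.best_estimator
    inc_params = {**best.best_params, "n_copies": best.best_params["n_copies"] + 1}
    inc = clone(base).set_params(**inc_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        inc.fit(X, y)
    record = {
        "objective": best.objective,
        "base_params": dict(best.best_params),
        "incremented_params": inc_params,
        "base_test_score": _score_fitted(base, Xt, yt, best.objective),
        "incremented_test_score": _score_fitted(inc, Xt, yt, best.objective),
    }
    return record


def default_roster(seed: int = 0) -> dict:
    """The 18 conventional baselines (scikit-learn implementations) plus the
    Helstrom classifier, each with a small tuning grid."""
    return {
        "AdaBoost": (AdaBoostClassifier(random_state=seed), {"n_estimators": [25, 50]}),
        "Bernoulli Naive Bayes": (BernoulliNB(), {"alpha": [0.1, 1.0]}),
        "Dummy Classifier": (DummyClassifier(strategy="prior"), {}),
        "Extra Trees": (ExtraTreesClassifier(random_state=seed), {"n_estimators": [50, 100]}),
        "Gaussian Naive Bayes": (GaussianNB(), {}),
        "Gradient Boosting": (
            GradientBoostingClassifier(random_state=seed),
            {"n_estimators": [50, 100]},
        ),
        "Linear Discriminant Analysis": (LinearDiscriminantAnalysis(), {}),
        "Logistic Regression": (LogisticRegression(max_iter=500), {"C": [0.1, 1.0, 10.0]}),
        "Multi Layer Perceptron": (
            MLPClassifier(max_iter=500, random_state=seed),
            {"hidden_layer_sizes": [(10,), (50,)]},
        ),
        "Nearest Centroid": (NearestCentroid(), {}),
        "Nearest Neighbors": (KNeighborsClassifier(), {"n_neighbors": [3, 5, 7]}),
        "Passive Aggressive Classifier": (
            PassiveAggressiveClassifier(random_state=seed),
            {"C": [0.1, 1.0]},
        ),
        "Perceptron": (Perceptron(random_state=seed), {"alpha": [1e-4, 1e-3]}),
        "Quadratic Discriminant Analysis": (QuadraticDiscriminantAnalysis(), {}),
        "Random Forest": (RandomForestClassifier(random_state=seed), {"n_estimators": [50, 100]}),
        "SVM (linear)": (SVC(kernel="linear", probability=True, random_state=seed),
                         {"C": [0.1, 1.0, 10.0]}),
        "SVM (polynomial)": (SVC(kernel="poly", probability=True, random_state=seed),
                             {"C": [0.1, 1.0, 10.0]}),
        "SVM (RBF)": (SVC(kernel="rbf", probability=True, random_state=seed),
                      {"C": [0.1, 1.0, 10.0]}),
        "Helstrom Quantum Classifier": (
            HelstromClassifier(standardize=True),
            {"__hqc_grid__": True},
        ),
    }


def usable_roster(roster: dict, objective: str) -> dict:
    """Drop score-less baselines when the objective is AUROC."""
    if objective != "auroc":
        return dict(roster)
    return {k: v for k, v in roster.items() if k not in SCORELESS_BASELINES}


def compare_classifiers(
    datasets,
    objective: str = "balanced_accuracy",
    roster: dict | None = None,
    feature_set_kind: str = "scalar",
    seed: int = 0,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Hypertune every roster entry on each dataset by the shared k-fold
    protocol and rank by mean test score.

    ``datasets`` is one ``(dev, test)`` pair or a list of pairs (pixel
    tables or (X, y) tuples).  Returns one row per classifier with the mean
    test score, per-dataset scores, and win/loss counts (pairwise strict
    comparisons against every other classifier on every dataset).
    """
    if isinstance(datasets, tuple) and len(datasets) == 2 and not isinstance(datasets[0], list):
        datasets = [datasets]
    roster = usable_roster(roster if roster is not None else default_roster(seed), objective)

    names = list(roster)
    scores = np.full((len(names), len(datasets)), np.nan)
    best_params: dict[str, list] = {name: [] for name in names}
    for j, (dev, test) in enumerate(datasets):
        for i, name in enumerate(names):
            est, grid = roster[name]
            if isinstance(grid, list):
                plist = grid
            elif grid.get("__hqc_grid__"):
                plist = hqc_param_grid(feature_set_kind)
            else:
                plist = list(ParameterGrid(grid)) if grid else [{}]
            try:
                res = grid_search(
                    dev, objective=objective, seed=seed, estimator=est,
                    param_grid=plist, n_folds=n_folds, test=test,
                )
            except Exception as exc:  # pragma: no cover - defensive skip
                warnings.warn(f"skipping {name!r} on dataset {j}: {exc}")
                best_params[name].append(None)
                continue
            value = (res.test_metrics.balanced_accuracy if objective == "balanced_accuracy"
                     else res.test_metrics.auroc)
            scores[i, j] = value
            best_params[name].append(res.best_params)

    wins = np.zeros(len(names), dtype=int)
    losses = np.zeros(len(names), dtype=int)
    for j in range(scores.shape[1]):
        col = scores[:, j]
        for i in range(len(names)):
            if np.isnan(col[i]):
                continue
            others = np.delete(col, i)
            wins[i] += int(np.sum(col[i] > others))
            losses[i] += int(np.sum(col[i] < others))

    table = pd.DataFrame(
        {
            "classifier": names,
            "mean_test_score": np.nanmean(scores, axis=1),
            "wins": wins,
            "losses": losses,
            "per_dataset_scores": [list(row) for row in scores],
            "best_params": [best_params[name] for name in names],
        }
    )
    return table.sort_values(
        "mean_test_score", ascending=False, kind="stable"
    ).reset_index(drop=True)
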