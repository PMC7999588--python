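"""Exhaustive 1- and 2-parameter classifier benchmarking under
leave-one-subject-out cross-validation.

Nine scikit-learn classifiers with fixed hyperparameters are evaluated on
every C(15,1) + C(15,2) = 120 feature combination. Features are z-scored per
fold on training rows only; the clinical label is the target and never a
predictor.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)

ALGORITHMS = ("DT", "AB", "NN", "NB", "KNN", "SVM_linear", "SVM_rbf", "RF", "QDA")


@dataclass(frozen=True)
class ClassifierSpec:
    """Immutable classifier recipe (fixed hyperparameters + seed)."""

    algorithm: str
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def build(self):
        a, s = self.algorithm, self.seed
        if a == "DT":
            return DecisionTreeClassifier(max_depth=5, random_state=s)
        if a == "AB":
            return AdaBoostClassifier(n_estimators=50, random_state=s)
        if a == "NN":
            return MLPClassifier(hidden_layer_sizes=(100,), max_iter=500,
                                 random_state=s)
        if a == "NB":
            return GaussianNB()
        if a == "KNN":
            return KNeighborsClassifier(n_neighbors=3)
        if a == "SVM_linear":
            return SVC(kernel="linear", C=0.025)
        if a == "SVM_rbf":
            return SVC(kernel="rbf", C=1.0)
        if a == "RF":
            return RandomForestClassifier(n_estimators=10, max_depth=5,
                                          random_state=s)
        if a == "QDA":
            return QuadraticDiscriminantAnalysis()
        raise AssertionError(a)

    def to_dict(self) -> dict:
        return {"algorithm": self.algorithm, "seed": self.seed}


@dataclass
class EvaluationResult:
    feature_names: tuple
    algorithm: str
    subject_ids: tuple
    per_fold_correct: np.ndarray      # bool, one entry per evaluated subject
    fold_stats: list                  # (train_index, mean, std) per fold
    dropped_subjects: tuple = ()

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_correct))

    @property
    def n_correct(self) -> int:
        return int(np.sum(self.per_fold_correct))


@dataclass
class DecisionGrid:
    feature_names: tuple
    xs: np.ndarray
    ys: np.ndarray
    classes: np.ndarray   # (len(ys), len(xs)) predicted class labels


# ---------------------------------------------------------------------------

def enumerate_feature_sets(names, max_size: int = 2) -> list:
    """All combinations of 1..max_size parameters in lexicographic order."""
    names = list(names)
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    ordered = sorted(names)
    combos = []
    for size in range(1, max_size + 1):
        combos.extend(itertools.combinations(ordered, size))
    return combos


def loso_folds(n_subjects: int) -> list:
    """Leave-one-subject-out partition: fold i tests subject i only."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for cross-validation")
    idx = np.arange(n_subjects)
    return [(idx[idx != i], np.array([i])) for i in idx]


def _standardize(train: np.ndarray):
    mean = train.mean(axis=0)
    std = train.std(axis=0, ddof=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def evaluate_model(features: pd.DataFrame, labels: pd.Series,
                   spec: ClassifierSpec, folds: list | None = None) -> EvaluationResult:
    """LOSO-evaluate one classifier on one feature combination.

    Standardization statistics are computed on training rows only. Subjects
    with a missing value in any selected feature are dropped (and logged)
    before fold construction.
    """
    X = features.to_numpy(float)
    y = labels.loc[features.index].to_numpy()
    ok = np.isfinite(X).all(axis=1)
    dropped = tuple(features.index[~ok])
    if dropped:
        log.info("dropping %d subject(s) with missing features %s: %s",
                 len(dropped), tuple(features.columns), dropped)
    X, y = X[ok], y[ok]
    ids = tuple(features.index[ok])
    if folds is None:
        folds = loso_folds(len(ids))

    correct = np.zeros(len(folds), dtype=bool)
    fold_stats = []
    for i, (tr, te) in enumerate(folds):
        mean, std = _standardize(X[tr])
        clf = spec.build()
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                clf.fit((X[tr] - mean) / std, y[tr])
                pred = clf.predict((X[te] - mean) / std)
        except (np.linalg.LinAlgError, ValueError) as e:
            # degenerate training fold (e.g. zero within-class variance);
            # count the fold as a miss rather than aborting the sweep
            log.warning("fold %d unfittable for %s on %s: %s", i,
                        spec.algorithm, tuple(features.columns), e)
            fold_stats.append((np.asarray(tr), mean, std))
            continue
        correct[i] = bool(np.all(pred == y[te]))
        fold_stats.append((np.asarray(tr), mean, std))
    return EvaluationResult(
        feature_names=tuple(features.columns), algorithm=spec.algorithm,
        subject_ids=ids, per_fold_correct=correct, fold_stats=fold_stats,
        dropped_subjects=dropped)


def audit_standardization(result: EvaluationResult, features: pd.DataFrame) -> None:
    """Recompute per-fold scaling from training rows; raise on contamination."""
    X = features[list(result.feature_names)].loc[list(result.subject_ids)].to_numpy(float)
    for tr, mean, std in result.fold_stats:
        ref_mean, ref_std = _standardize(X[tr])
        if not (np.allclose(mean, ref_mean) and np.allclose(std, ref_std)):
            raise AssertionError("standardization statistics leak beyond the "
                                 "training fold")


def evaluate_all(features: pd.DataFrame, labels: pd.Series, seed: int = 0,
                 max_size: int = 2, algorithms=ALGORITHMS) -> list:
    """Evaluate every feature combination with every classifier."""
    results = []
    for combo in enumerate_feature_sets(features.columns, max_size):
        sub = features[list(combo)]
        for algo in algorithms:
            results.append(evaluate_model(sub, labels, ClassifierSpec(algo, seed)))
    return results


def rank_results(results: list) -> pd.DataFrame:
    """Leaderboard: per feature combination, the best mean accuracy and all
    algorithms attaining it; sorted by accuracy descending."""
    if not results:
        raise ValueError("no results to rank")
    rows = {}
    for r in results:
        key = r.feature_names
        entry = rows.setdefault(key, {"mean_accuracy": -1.0, "algorithms": []})
        acc = r.mean_accuracy
        if acc > entry["mean_accuracy"] + 1e-12:
            entry["mean_accuracy"] = acc
            entry["algorithms"] = [r.algorithm]
        elif abs(acc - entry["mean_accuracy"]) <= 1e-12:
            entry["algorithms"].append(r.algorithm)
    records = [{
        "features": ", ".join(k),
        "n_features": len(k),
        "mean_accuracy": v["mean_accuracy"],
        "algorithms": ", ".join(sorted(set(v["algorithms"]))),
    } for k, v in rows.items()]
    df = pd.DataFrame.from_records(records)
    return df.sort_values(["mean_accuracy", "features"],
                          ascending=[False, True]).reset_index(drop=True)


def fit_full(features: pd.DataFrame, labels: pd.Series, spec: ClassifierSpec):
    """Fit a (scaler, classifier) pair on all rows, for decision grids."""
    X = features.to_numpy(float)
    ok = np.isfinite(X).all(axis=1)
    X = X[ok]
    y = labels.loc[features.index].to_numpy()[ok]
    mean, std = _standardize(X)
    clf = spec.build()
    clf.fit((X - mean) / std, y)

    def predict(points):
        return clf.predict((np.asarray(points, float) - mean) / std)

    return predict


def decision_grid(predict, feature_names, bounds, resolution: int = 100) -> DecisionGrid:
    """Predicted class at each node of a regular 2D grid.

    ``bounds`` = (x_min, x_max, y_min, y_max); must be non-degenerate and
    should cover the observed feature range plus a margin.
    """
    x0, x1, y0, y1 = bounds
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate grid bounds")
    xs = np.linspace(x0, x1, resolution)
    ys = np.linspace(y0, y1, resolution)
    XX, YY = np.meshgrid(xs, ys)
    Z = predict(np.column_stack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    return DecisionGrid(feature_names=tuple(feature_names), xs=xs, ys=ys,
                        classes=Z)


def grid_bounds(features: pd.DataFrame, margin: float = 0.15) -> tuple:
    """Observed 2-feature range expanded by a relative margin."""
    lo = features.min()
    hi = features.max()
    span = (hi - lo).replace(0, 1.0)
    lo = lo - margin * span
    hi = hi + margin * span
    (x0, y0), (x1, y1) = lo.to_numpy(), hi.to_numpy()
    return float(x0), float(x1), float(y0), float(y1)
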