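"""Supervised species classification with stratified k-fold cross-validation.

The nearest-neighbour family is implemented natively (exhaustive Euclidean
search, majority vote with deterministic tie-breaks).  The tree-ensemble,
multinomial-logistic and margin-based families are delegated to
scikit-learn estimators behind a fit/predict-probabilities contract.

Reported metrics follow the conventions of attribute/label workbenches:
accuracy is the percentage of test instances predicted correctly; RMSE is
``sqrt(sum_i sum_c (p_ic - y_ic)^2 / (N * C))`` against one-hot truth;
per-class TPR/FPR are pooled over folds and repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError
from .features import FeatureMatrix

FAMILIES = ("nearest-neighbor", "tree-ensemble", "multinomial-logistic", "margin-based")

#: CLI shorthand -> family
FAMILY_ALIASES = {
    "knn": "nearest-neighbor",
    "rf": "tree-ensemble",
    "mcc": "multinomial-logistic",
    "svm": "margin-based",
}


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    params: dict = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self):
        family = FAMILY_ALIASES.get(self.family, self.family)
        object.__setattr__(self, "family", family)
        if family not in FAMILIES:
            raise ConfigError(f"unknown classifier family {self.family!r}")
        if family == "nearest-neighbor":
            nn = self.params.get("nn", 1)
            if not (isinstance(nn, (int, np.integer)) and nn >= 1):
                raise ConfigError("nearest-neighbor 'nn' must be a positive integer")


@dataclass
class CVResult:
    """Everything measured by one repeated cross-validation run."""

    classifier: ClassifierSpec
    n_folds: int
    repeats: int
    fold_assignments: np.ndarray  # (repeats, N)
    predictions: np.ndarray  # (repeats, N) object array of labels
    probabilities: np.ndarray  # (repeats, N, C)
    classes: list[str]
    per_run_accuracies: list[float]  # folds * repeats values, in schedule order
    accuracy_pct: float
    rmse: float
    per_class: pd.DataFrame  # index species, columns tpr / fpr
    species_any_correct_pct: float
    species_all_correct_pct: float
    tpr1_species_pct: float
    fpr_degenerate: bool = False


def stratified_folds(labels, n_folds: int = 10, seed: int = 1) -> np.ndarray:
    """Per-class round-robin fold assignment after a seeded shuffle.

    Classes are staggered (each class starts filling where the previous one
    stopped) so classes smaller than ``n_folds`` spread evenly instead of
    piling into fold 0.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if n_folds < 2:
        raise ConfigError("n_folds must be >= 2")
    if n < n_folds:
        raise DataError(f"cannot make {n_folds} folds from {n} instances")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    offset = 0
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, t in enumerate(idx):
            folds[t] = (offset + j) % n_folds
        offset += idx.size
    return folds


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    nn: int = 1,
    classes: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive Euclidean nearest-neighbour prediction.

    Majority vote among the ``nn`` nearest training points; vote ties break
    to the class with the smallest aggregate neighbour distance, then to the
    class seen first in the training data.  Probabilities are neighbour
    class frequencies, laid out over ``classes`` (defaults to the classes in
    the training set, first-seen order).
    """
    train_y = np.asarray(train_y, dtype=object)
    if train_X.shape[0] == 0:
        raise DataError("empty training set")
    if classes is None:
        classes = list(pd.unique(train_y))
    class_index = {c: i for i, c in enumerate(classes)}
    first_seen = {}
    for label in train_y:
        first_seen.setdefault(label, len(first_seen))
    nn = min(nn, train_X.shape[0])
    D = cdist(np.asarray(test_X, float), np.asarray(train_X, float))
    preds = np.empty(test_X.shape[0], dtype=object)
    probs = np.zeros((test_X.shape[0], len(classes)))
    for i in range(test_X.shape[0]):
        order = np.argsort(D[i], kind="stable")[:nn]
        votes: dict[str, int] = {}
        agg: dict[str, float] = {}
        for j in order:
            label = train_y[j]
            votes[label] = votes.get(label, 0) + 1
            agg[label] = agg.get(label, 0.0) + D[i, j]
        best = max(votes.values())
        tied = [c for c, v in votes.items() if v == best]
        tied.sort(key=lambda c: (agg[c], first_seen[c]))
        preds[i] = tied[0]
        for label, v in votes.items():
            if label in class_index:
                probs[i, class_index[label]] = v / nn
    return preds, probs


def rmse_from_probabilities(probs: np.ndarray, truth_idx: np.ndarray) -> float:
    """Workbench-style RMSE: per-instance, per-class normalized squared error."""
    probs = np.asarray(probs, float)
    n, c = probs.shape
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), truth_idx] = 1.0
    return float(np.sqrt(np.sum((probs - onehot) ** 2) / (n * c)))


def _make_estimator(spec: ClassifierSpec):
    if spec.family == "tree-ensemble":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=spec.params.get("n_estimators", 100),
            random_state=spec.seed,
        )
    if spec.family == "multinomial-logistic":
        from sklearn.linear_model import LogisticRegression

        ridge = spec.params.get("ridge", 1e-8)
        return LogisticRegression(C=1.0 / max(ridge, 1e-12), max_iter=500)
    if spec.family == "margin-based":
        from sklearn.svm import SVC

        return SVC(
            kernel=spec.params.get("kernel", "poly"),
            degree=spec.params.get("degree", 1),
            C=spec.params.get("C", 1.0),
            probability=True,
            random_state=spec.seed,
        )
    raise ConfigError(f"no estimator for family {spec.family!r}")


def evaluate_cv(
    fm: FeatureMatrix,
    spec: ClassifierSpec,
    n_folds: int = 10,
    repeats: int = 1,
    seed: int | None = None,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of one classifier.

    Repeat ``r`` uses fold seed ``seed + r`` so that two classifiers
    evaluated with the same seed see the identical fold schedule (the
    precondition of the corrected paired t-test).
    """
    if seed is None:
        seed = spec.seed
    X = np.asarray(fm.values, float)
    y = np.asarray(fm.labels, dtype=object)
    n = y.size
    classes = sorted(set(y))
    class_index = {c: i for i, c in enumerate(classes)}
    truth_idx = np.array([class_index[label] for label in y])

    fold_assignments = np.empty((repeats, n), dtype=int)
    predictions = np.empty((repeats, n), dtype=object)
    probabilities = np.zeros((repeats, n, len(classes)))
    per_run_accuracies: list[float] = []

    for r in range(repeats):
        folds = stratified_folds(y, n_folds, seed + r)
        fold_assignments[r] = folds
        for f in range(n_folds):
            test = folds == f
            train = ~test
            if not test.any():
                per_run_accuracies.append(float("nan"))
                continue
            if spec.family == "nearest-neighbor":
                preds, probs = knn_predict(
                    X[train], y[train], X[test], nn=spec.params.get("nn", 1),
                    classes=None,
                )
                train_classes = list(pd.unique(y[train]))
            else:
                est = _make_estimator(spec)
                est.fit(X[train], y[train])
                probs = est.predict_proba(X[test])
                preds = np.asarray(est.classes_)[np.argmax(probs, axis=1)]
                train_classes = list(est.classes_)
            predictions[r, test] = preds
            cols = [class_index[c] for c in train_classes]
            probabilities[r, np.flatnonzero(test)[:, None], np.array(cols)[None, :]] = probs
            per_run_accuracies.append(float(np.mean(preds == y[test])) * 100.0)

    flat_true = np.tile(truth_idx, repeats)
    flat_pred = np.array(
        [class_index[p] for p in predictions.ravel()], dtype=int
    )
    correct = flat_pred == flat_true
    accuracy_pct = 100.0 * float(np.mean(correct))
    rmse = rmse_from_probabilities(
        probabilities.reshape(-1, len(classes)), flat_true
    )

    # pooled per-class confusion
    rows = []
    degenerate = len(classes) < 2
    for ci, cls in enumerate(classes):
        pos = flat_true == ci
        tp = int(np.sum(pos & (flat_pred == ci)))
        fn = int(np.sum(pos & (flat_pred != ci)))
        fp = int(np.sum(~pos & (flat_pred == ci)))
        tn = int(np.sum(~pos & (flat_pred != ci)))
        tpr = tp / (tp + fn) if (tp + fn) else float("nan")
        fpr = fp / (fp + tn) if (fp + tn) else float("nan")
        rows.append({"species": cls, "tpr": tpr, "fpr": fpr})
    per_class = pd.DataFrame(rows).set_index("species")

    by_class_correct = {
        cls: correct[flat_true == class_index[cls]] for cls in classes
    }
    n_any = sum(1 for v in by_class_correct.values() if v.any())
    n_all = sum(1 for v in by_class_correct.values() if v.all())
    n_tpr1 = int((per_class["tpr"] == 1.0).sum())

    return CVResult(
        classifier=spec,
        n_folds=n_folds,
        repeats=repeats,
        fold_assignments=fold_assignments,
        predictions=predictions,
        probabilities=probabilities,
        classes=classes,
        per_run_accuracies=per_run_accuracies,
        accuracy_pct=accuracy_pct,
        rmse=rmse,
        per_class=per_class,
        species_any_correct_pct=100.0 * n_any / len(classes),
        species_all_correct_pct=100.0 * n_all / len(classes),
        tpr1_species_pct=100.0 * n_tpr1 / len(classes),
        fpr_degenerate=degenerate,
    )


def evaluation_report(results: list[CVResult], names: list[str]) -> pd.DataFrame:
    """Summary matrix: one row per named run, in input order."""
    if len(results) != len(names):
        raise ValueError("results and names must align")
    rows = []
    for name, res in zip(names, results):
        rows.append(
            {
                "name": name,
                "accuracy_pct": res.accuracy_pct,
                "rmse": res.rmse,
                "species_any_correct_pct": res.species_any_correct_pct,
                "species_all_correct_pct": res.species_all_correct_pct,
                "tpr1_species_pct": res.tpr1_species_pct,
            }
        )
    return pd.DataFrame(rows).set_index("name")
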