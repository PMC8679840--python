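"""Four-algorithm 3-class modeling with cross-cohort evaluation.

Algorithms: linear one-vs-rest SVM (hinge loss, L2), AdaBoost over decision
stumps (50 rounds), random forest (100 trees), and a 64-32-16 feed-forward
multilayer perceptron with a 3-unit softmax head trained with cross-entropy
(adam, learning rate 1e-3, 100 epochs, batch 32).  All randomness flows from
one integer seed.

Evaluation reports a 3x3 confusion matrix, accuracy and per-class
one-vs-rest AUC for each held-out cohort, under two protocols:

* protocol A — train on a pooled stratified 70% split, test on the two 30%
  cohort partitions;
* protocol B — train on one cohort, test on the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .containers import CohortAnnotation, FeatureTable

ALGORITHMS = ("svm", "adaboost", "rf", "nn")
CLASS_NAMES = ("CON", "MCI", "AD")


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "svm":
        return LinearSVC(loss="hinge", dual=True, random_state=seed, max_iter=20000)
    if algorithm == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=50,
            random_state=seed,
        )
    if algorithm == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if algorithm == "nn":
        return MLPClassifier(
            hidden_layer_sizes=(64, 32, 16),
            solver="adam",
            learning_rate_init=1e-3,
            batch_size=32,
            max_iter=100,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


@dataclass
class FittedModel:
    """A fitted classifier plus the feature names/order it was trained on."""

    algorithm: str
    estimator: object
    feature_names: list[str]
    classes: np.ndarray

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous per-class scores: decision margins for the SVM, class
        probabilities otherwise."""
        if self.algorithm == "svm":
            return np.asarray(self.estimator.decision_function(X))
        return np.asarray(self.estimator.predict_proba(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))


def train_models(
    F: FeatureTable,
    labels: np.ndarray,
    algorithms: tuple[str, ...] = ALGORITHMS,
    seed: int = 0,
) -> dict[str, FittedModel]:
    """Fit the requested algorithms on features x samples ``F``.

    Labels are the ordinal stage codes 0/1/2; every class present must have
    at least 2 training samples.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 3:
        raise ValueError(f"training labels must contain all 3 classes, got {list(classes)}")
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 training samples")
    X = F.values.to_numpy(dtype=float).T
    fitted: dict[str, FittedModel] = {}
    for algo in algorithms:
        est = _make_estimator(algo, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on small nets
            est.fit(X, y)
        fitted[algo] = FittedModel(algo, est, list(F.feature_names), np.asarray(est.classes_))
    return fitted


def ovr_auc(scores: np.ndarray, labels: np.ndarray, classes: np.ndarray | None = None) -> dict:
    """Per-class one-vs-rest AUC via the Mann-Whitney U statistic.

    ``scores`` is (n_samples, n_classes); column k scores class k against the
    rest.  AUC_k = U / (n_pos * n_neg) with ties counted 1/2.  A class with
    no positives or no negatives gets ``None`` (flagged degenerate).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if scores.ndim != 2:
        raise ValueError("scores must be (n_samples, n_classes)")
    if classes is None:
        classes = np.unique(y)
    out: dict = {}
    for k, cls in enumerate(classes):
        pos = scores[y == cls, k]
        neg = scores[y != cls, k]
        if len(pos) == 0 or len(neg) == 0:
            out[int(cls)] = None
            continue
        # U = sum over (pos, neg) pairs of 1[pos>neg] + 0.5 * 1[pos==neg]
        diff = pos[:, None] - neg[None, :]
        u = (diff > 0).sum() + 0.5 * (diff == 0).sum()
        out[int(cls)] = float(u / (len(pos) * len(neg)))
    return out


@dataclass
class ModelReport:
    """Per-algorithm evaluation across held-out cohorts."""

    algorithm: str
    confusion: dict[str, pd.DataFrame] = field(default_factory=dict)  # cohort -> 3x3
    accuracy: dict[str, float] = field(default_factory=dict)
    auc: dict[str, dict] = field(default_factory=dict)  # cohort -> class -> AUC
    recall: dict[str, dict] = field(default_factory=dict)

    @property
    def macro_accuracy(self) -> float:
        """Unweighted mean of the per-cohort test accuracies."""
        return float(np.mean(list(self.accuracy.values())))

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "accuracy": self.accuracy,
            "macro_accuracy": self.macro_accuracy,
            "auc": self.auc,
            "recall": self.recall,
            "confusion": {c: m.to_dict(orient="split") for c, m in self.confusion.items()},
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> pd.DataFrame:
    names = [CLASS_NAMES[int(c)] if int(c) < len(CLASS_NAMES) else str(c) for c in classes]
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return pd.DataFrame(mat, index=pd.Index(names, name="true"), columns=pd.Index(names, name="predicted"))


def evaluate(
    model: FittedModel,
    F_test: FeatureTable,
    labels_test: np.ndarray,
    annotation: CohortAnnotation | None = None,
) -> ModelReport:
    """Confusion matrix, accuracy, per-class OvR AUC and recall per test cohort.

    With no annotation the whole test set is treated as one cohort "test".
    Test features must match the training features in name and order.
    """
    if list(F_test.feature_names) != model.feature_names:
        missing = set(model.feature_names) - set(F_test.feature_names)
        extra = set(F_test.feature_names) - set(model.feature_names)
        raise ValueError(
            f"test features do not match training features; missing={sorted(missing)[:5]}, "
            f"extra={sorted(extra)[:5]} (order must match too)"
        )
    y = np.asarray(labels_test)
    sample_ids = F_test.sample_ids
    if annotation is not None:
        cohort_of = annotation.cohort
        cohorts = {str(c): [s for s in sample_ids if cohort_of.get(s) == c] for c in sorted(set(cohort_of.loc[sample_ids]))}
    else:
        cohorts = {"test": list(sample_ids)}

    report = ModelReport(algorithm=model.algorithm)
    pos_of = {s: i for i, s in enumerate(sample_ids)}
    X_all = F_test.values.to_numpy(dtype=float).T
    for cohort, ids in cohorts.items():
        idx = [pos_of[s] for s in ids]
        X = X_all[idx]
        yt = y[idx]
        pred = model.predict(X)
        conf = _confusion(yt, pred, model.classes)
        report.confusion[cohort] = conf
        report.accuracy[cohort] = float((pred == yt).mean())
        report.auc[cohort] = ovr_auc(model.scores(X), yt, model.classes)
        rec = {}
        for c in model.classes:
            n_c = int((yt == c).sum())
            name = CLASS_NAMES[int(c)]
            rec[name] = float(((pred == c) & (yt == c)).sum() / n_c) if n_c else None
        report.recall[cohort] = rec
    return report


def split_protocol_a(
    F: FeatureTable,
    annotation: CohortAnnotation,
    test_size: float = 0.3,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Pooled stratified train/test split; stratification by diagnosis x cohort."""
    ids = F.sample_ids
    strata = [
        f"{annotation.diagnosis[s]}|{annotation.cohort[s]}" for s in ids
    ]
    train_ids, test_ids = train_test_split(
        ids, test_size=test_size, stratify=strata, random_state=seed
    )
    return list(train_ids), list(test_ids)


def run_protocols(
    F: FeatureTable,
    annotation: CohortAnnotation,
    algorithms: tuple[str, ...] = ALGORITHMS,
    seed: int = 0,
    test_size: float = 0.3,
) -> dict[str, dict[str, ModelReport]]:
    """Run both evaluation protocols for every algorithm.

    Returns {"protocol_a": {algo: report}, "protocol_b": {algo: report}}.
    Protocol A trains on a pooled stratified 70% and reports each cohort's
    30% partition separately; protocol B trains on the first cohort and
    tests on the second.
    """
    from .containers import stage_labels

    labels = stage_labels(annotation, F.sample_ids)
    out: dict[str, dict[str, ModelReport]] = {"protocol_a": {}, "protocol_b": {}}

    train_ids, test_ids = split_protocol_a(F, annotation, test_size=test_size, seed=seed)
    F_train, F_test = F.subset_samples(train_ids), F.subset_samples(test_ids)
    y_train = stage_labels(annotation, train_ids)
    y_test = stage_labels(annotation, test_ids)
    models = train_models(F_train, y_train, algorithms, seed=seed)
    for algo, model in models.items():
        out["protocol_a"][algo] = evaluate(model, F_test, y_test, annotation.subset(test_ids))

    cohort_ids = sorted(set(annotation.cohort))
    if len(cohort_ids) >= 2:
        first, second = cohort_ids[0], cohort_ids[1]
        ids1 = [s for s in F.sample_ids if annotation.cohort[s] == first]
        ids2 = [s for s in F.sample_ids if annotation.cohort[s] == second]
        F1, F2 = F.subset_samples(ids1), F.subset_samples(ids2)
        y1, y2 = stage_labels(annotation, ids1), stage_labels(annotation, ids2)
        models_b = train_models(F1, y1, algorithms, seed=seed)
        for algo, model in models_b.items():
            out["protocol_b"][algo] = evaluate(model, F2, y2, annotation.subset(ids2))
    return out
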