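"""Hyperdimensional classifier: class vectors, retraining, prediction, k-fold CV.

Training bundles (sums) the encoded hypervectors of each class's samples
into a single integer class vector.  Bundling introduces crosstalk noise, so
an error-mitigation pass ("retraining") iterates over the training samples
in dataset order: each misclassified sample's vector is subtracted from the
wrongly predicted class vector and added to its true class vector.  Passes
stop when the per-pass error count stops changing or the cap R is reached.
Prediction returns the class whose vector is most cosine-similar to the
encoded query; exact ties go to the first class in declared label order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .encoding import LabeledDataset, QuantizationScheme, encode_matrix
from .vsa import LevelEncoding, generate_levels

__all__ = [
    "HDModel",
    "EvaluationReport",
    "RetrainResult",
    "FoldPlan",
    "fit_classes",
    "predict",
    "retrain",
    "evaluate",
    "make_folds",
    "cross_validate",
    "CrossValidationResult",
]


@dataclass
class HDModel:
    """One integer class vector per class; the trained classifier."""

    class_labels: list
    class_vectors: np.ndarray  # (n_classes, d) int64
    retrain_iterations_used: int = 0

    def __post_init__(self):
        self.class_vectors = np.asarray(self.class_vectors, dtype=np.int64)
        if self.class_vectors.ndim != 2:
            raise ValueError("class_vectors must be 2-D")
        if len(self.class_labels) != self.class_vectors.shape[0]:
            raise ValueError("one class vector per class label is required")

    @property
    def d(self) -> int:
        return int(self.class_vectors.shape[1])


def _as_matrix(encoded) -> np.ndarray:
    e = np.asarray(encoded)
    if e.ndim == 1:
        e = e[None, :]
    if e.ndim != 2:
        raise ValueError("encoded samples must be a vector or a 2-D matrix")
    return e


def fit_classes(encoded, labels, class_labels: list | None = None) -> HDModel:
    """Bundle each class's encoded training samples into its class vector."""
    e = _as_matrix(encoded)
    y = np.asarray(labels, dtype=object)
    if e.shape[0] == 0:
        raise ValueError("cannot fit on an empty training set")
    if y.shape[0] != e.shape[0]:
        raise ValueError("labels length does not match the number of samples")
    if class_labels is None:
        class_labels = sorted(set(y.tolist()))
    vectors = np.zeros((len(class_labels), e.shape[1]), dtype=np.int64)
    for c, label in enumerate(class_labels):
        mask = y == label
        if not mask.any():
            raise ValueError(f"class {label!r} has no training samples")
        vectors[c] = e[mask].sum(axis=0, dtype=np.int64)
    return HDModel(class_labels=list(class_labels), class_vectors=vectors)


def _similarities(class_vectors: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Cosine of every sample against every class vector; zero norms give 0."""
    vf = class_vectors.astype(np.float64)
    ef = encoded.astype(np.float64)
    vnorm = np.linalg.norm(vf, axis=1)
    enorm = np.linalg.norm(ef, axis=1)
    if np.any(vnorm == 0.0) or np.any(enorm == 0.0):
        warnings.warn(
            "zero vector encountered in similarity computation; treating its "
            "cosine as 0",
            RuntimeWarning,
        )
    dots = ef @ vf.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = dots / np.outer(enorm, vnorm)
    sims[~np.isfinite(sims)] = 0.0
    return sims


def predict(model: HDModel, encoded):
    """Label(s) of the most cosine-similar class vector (ties: first listed)."""
    if len(model.class_labels) == 0:
        raise ValueError("model has no classes")
    e = _as_matrix(encoded)
    if e.shape[1] != model.d:
        raise ValueError("encoded sample dimension does not match the model")
    winners = np.argmax(_similarities(model.class_vectors, e), axis=1)
    labels = [model.class_labels[i] for i in winners]
    return labels[0] if np.asarray(encoded).ndim == 1 else labels


@dataclass
class RetrainResult:
    model: HDModel
    iterations_used: int
    final_error_count: int
    conserved: bool  # sum of all class vectors unchanged by retraining


def _count_errors(class_vectors, class_labels, encoded, y_idx) -> int:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sims = _similarities(class_vectors, encoded)
    return int(np.sum(np.argmax(sims, axis=1) != y_idx))


def retrain(model: HDModel, encoded, labels, max_iterations: int) -> RetrainResult:
    """Iterative error mitigation over the training set in dataset order.

    Stops when a pass's error count equals the previous pass's count or
    after ``max_iterations`` passes.  The element-wise sum of all class
    vectors is conserved (each adjustment moves the same sample vector
    between two classes); the result reports that invariant.
    """
    if max_iterations < 0:
        raise ValueError("max_iterations must be >= 0")
    e = _as_matrix(encoded).astype(np.int64)
    y = np.asarray(labels, dtype=object)
    label_index = {label: i for i, label in enumerate(model.class_labels)}
    try:
        y_idx = np.asarray([label_index[label] for label in y], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"label {err} not among the model's classes") from None

    vectors = model.class_vectors.copy()
    total_before = vectors.sum(axis=0)
    ef = e.astype(np.float64)

    prev_errors = 0
    curr_errors = _count_errors(vectors, model.class_labels, e, y_idx)
    iterations = 0
    while curr_errors != prev_errors and iterations < max_iterations:
        vf = vectors.astype(np.float64)
        norms = np.linalg.norm(vf, axis=1)
        for i in range(e.shape[0]):
            dots = vf @ ef[i]
            with np.errstate(divide="ignore", invalid="ignore"):
                sims = np.where(norms > 0.0, dots / norms, 0.0)
            pred = int(np.argmax(sims))
            true = int(y_idx[i])
            if pred != true:
                vectors[pred] -= e[i]
                vectors[true] += e[i]
                vf[pred] -= ef[i]
                vf[true] += ef[i]
                norms[pred] = np.linalg.norm(vf[pred])
                norms[true] = np.linalg.norm(vf[true])
        prev_errors = curr_errors
        curr_errors = _count_errors(vectors, model.class_labels, e, y_idx)
        iterations += 1

    conserved = bool(np.array_equal(vectors.sum(axis=0), total_before))
    new_model = HDModel(
        class_labels=list(model.class_labels),
        class_vectors=vectors,
        retrain_iterations_used=iterations,
    )
    return RetrainResult(new_model, iterations, curr_errors, conserved)


@dataclass
class EvaluationReport:
    """Accuracy, one-vs-rest precision/recall/F1, and the confusion matrix."""

    class_labels: list
    confusion: np.ndarray  # (C, C) counts, rows = true, cols = predicted
    accuracy: float
    precision: dict
    recall: dict
    f1: dict
    undefined: list  # (class, metric) pairs where a denominator was zero

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())


def evaluate(model: HDModel, encoded, labels) -> EvaluationReport:
    """Accuracy = correctly classified / total on the given (test) samples."""
    e = _as_matrix(encoded)
    y = np.asarray(labels, dtype=object)
    if e.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty test set")
    if y.shape[0] != e.shape[0]:
        raise ValueError("labels length does not match the number of samples")
    label_index = {label: i for i, label in enumerate(model.class_labels)}
    if not all(label in label_index for label in y):
        raise ValueError("test labels contain a class unknown to the model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        preds = np.argmax(_similarities(model.class_vectors, e), axis=1)
    y_idx = np.asarray([label_index[label] for label in y])
    n_classes = len(model.class_labels)
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (y_idx, preds), 1)
    accuracy = float(np.trace(confusion) / confusion.sum())
    precision, recall, f1, undefined = {}, {}, {}, []
    for c, label in enumerate(model.class_labels):
        tp = confusion[c, c]
        fp = confusion[:, c].sum() - tp
        fn = confusion[c, :].sum() - tp
        if tp + fp == 0:
            precision[label] = 0.0
            undefined.append((label, "precision"))
        else:
            precision[label] = float(tp / (tp + fp))
        if tp + fn == 0:
            recall[label] = 0.0
            undefined.append((label, "recall"))
        else:
            recall[label] = float(tp / (tp + fn))
        denom = precision[label] + recall[label]
        if denom == 0.0:
            f1[label] = 0.0
            if (label, "precision") in undefined and (label, "recall") in undefined:
                undefined.append((label, "f1"))
        else:
            f1[label] = float(2 * precision[label] * recall[label] / denom)
    return EvaluationReport(
        class_labels=list(model.class_labels),
        confusion=confusion,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        undefined=undefined,
    )


@dataclass(frozen=True)
class FoldPlan:
    """Class-stratified k-fold split, a pure function of (labels, k, seed)."""

    k: int
    test_index_sets: tuple  # tuple of int64 arrays partitioning range(n)
    seed: int

    def splits(self, n: int):
        """Yield (train_indices, test_indices) pairs."""
        all_idx = np.arange(n)
        for test in self.test_index_sets:
            mask = np.ones(n, dtype=bool)
            mask[test] = False
            yield all_idx[mask], np.asarray(test)


def make_folds(labels, k: int, seed: int) -> FoldPlan:
    y = np.asarray(labels, dtype=object)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if counts.min() < k:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than k={k}; "
            "stratified folding is impossible"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    tests = tuple(
        np.asarray(test, dtype=np.int64)
        for _, test in skf.split(np.zeros(len(y)), y.astype(str))
    )
    return FoldPlan(k=int(k), test_index_sets=tests, seed=int(seed))


@dataclass
class CrossValidationResult:
    fold_plan: FoldPlan
    reports: list  # EvaluationReport per fold
    fold_accuracies: list
    mean_accuracy: float
    fold_retrain_iterations: list
    mean_retrain_iterations: float
    conserved: bool


def cross_validate(
    dataset: LabeledDataset,
    k: int = 5,
    *,
    dimension: int = 10_000,
    n_levels: int = 1000,
    retrain_iterations: int = 10,
    seed: int = 0,
    levels: LevelEncoding | None = None,
    fold_plan: FoldPlan | None = None,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of the full encode/fit/retrain loop.

    The quantization range is fitted on each fold's training portion only;
    the level-vector family is generated once from the seed and shared by
    every fold, so accuracies of different runs on the same seed are
    directly comparable.
    """
    if levels is None:
        levels = generate_levels(dimension, n_levels, seed)
    if fold_plan is None:
        fold_plan = make_folds(dataset.labels, k, seed)
    positions = np.arange(dataset.n_features)
    class_labels = dataset.class_labels
    reports, accs, iters = [], [], []
    conserved = True
    for train_idx, test_idx in fold_plan.splits(dataset.n_samples):
        scheme = QuantizationScheme.from_values(
            dataset.values[train_idx], levels.n_levels
        )
        enc_train = encode_matrix(dataset.values[train_idx], positions, levels, scheme)
        enc_test = encode_matrix(dataset.values[test_idx], positions, levels, scheme)
        model = fit_classes(enc_train, dataset.labels[train_idx], class_labels)
        result = retrain(model, enc_train, dataset.labels[train_idx], retrain_iterations)
        conserved = conserved and result.conserved
        report = evaluate(result.model, enc_test, dataset.labels[test_idx])
        reports.append(report)
        accs.append(report.accuracy)
        iters.append(result.iterations_used)
    return CrossValidationResult(
        fold_plan=fold_plan,
        reports=reports,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        fold_retrain_iterations=iters,
        mean_retrain_iterations=float(np.mean(iters)),
        conserved=conserved,
    )
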