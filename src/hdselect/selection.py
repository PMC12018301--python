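"""Stepwise backward variable elimination over hyperdimensional models.

The wrapper starts from the full feature set.  Each iteration evaluates all
leave-one-feature-out candidate subsets by cross-validated HD classification,
discards candidates whose mean accuracy falls below the accuracy threshold T,
and permanently removes *every* feature whose exclusion scored within the
accuracy-uncertainty band of the iteration's best candidate, i.e. at least

    best_accuracy * (1 - u / 100)

(the band is relative: "best minus its u%").  The run terminates when

* the initial full-set model scores below T (nothing is removed),
* no candidate reaches T,
* an iteration's best accuracy falls below the previous iteration's best by
  more than the uncertainty band (the iteration is rejected and its removals
  are not applied), or
* the feature set is exhausted.

With u = 0 the band collapses to the single best candidate and the
termination rule to a strict decrease, recovering classic one-feature-per-step
backward elimination.  Every candidate model is recorded in the trace, which
also supports the "suboptimal frontier": the evaluated model with the fewest
features whose accuracy still exceeds a floor (default 70%) -- often a far
smaller signature than the best model at a modest accuracy cost.

Accuracies in this module are percentages in [0, 100].
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .classifier import evaluate, fit_classes, make_folds, retrain
from .encoding import LabeledDataset, QuantizationScheme, feature_contributions
from .vsa import generate_levels

__all__ = [
    "SelectionConfig",
    "SubsetEvaluation",
    "CandidateRecord",
    "IterationRecord",
    "SelectionResult",
    "FrontierModel",
    "acceptance_cutoff",
    "display_percent",
    "backward_eliminate",
    "forward_select_order",
    "suboptimal_frontier",
    "HDSubsetEvaluator",
    "write_trace_jsonl",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of a selection run (accuracies/thresholds in percent)."""

    accuracy_threshold: float = 60.0
    accuracy_uncertainty: float = 1.0
    dimension: int = 10_000
    n_levels: int = 1000
    retrain_iterations: int = 10
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.accuracy_threshold <= 100.0:
            raise ValueError("accuracy_threshold must be in [0, 100]")
        if not 0.0 <= self.accuracy_uncertainty <= 100.0:
            raise ValueError("accuracy_uncertainty must be in [0, 100]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.retrain_iterations < 0:
            raise ValueError("retrain_iterations must be >= 0")


def acceptance_cutoff(best_accuracy: float, uncertainty: float) -> float:
    """Band cutoff: the best accuracy minus its ``uncertainty`` percent.

    The comparison value is exact (no rounding); use ``display_percent`` for
    the floored integer percent shown in reports.
    """
    return best_accuracy * (1.0 - uncertainty / 100.0)


def display_percent(x: float) -> int:
    """Floored integer percent used for display."""
    return math.floor(x)


@dataclass
class SubsetEvaluation:
    """Cross-validated score of one candidate feature subset."""

    mean_accuracy: float  # percent
    fold_accuracies: list  # percent
    mean_retrain_iterations: float
    conserved: bool = True


@dataclass
class CandidateRecord:
    excluded_feature: str | None  # None for the initial full-set model
    mean_accuracy: float
    fold_accuracies: list
    mean_retrain_iterations: float


@dataclass
class IterationRecord:
    iteration: int
    candidates: list  # CandidateRecord, in evaluation order
    best_accuracy: float | None
    band_cutoff: float | None
    removed_features: list
    accepted: bool


@dataclass
class SelectionResult:
    feature_names: list  # original feature order
    selected: list  # S_final, original order
    excluded: list  # bucket B, removal order
    initial: CandidateRecord
    trace: list  # IterationRecord
    best_features: list  # feature set of the best evaluated model
    best_accuracy: float
    models_evaluated: int
    terminated_reason: str

    def final_accepted_best_accuracy(self) -> float:
        """Best accuracy of the last accepted elimination iteration.

        Falls back to the initial full-set accuracy when no iteration was
        accepted.
        """
        accepted = [r for r in self.trace if r.accepted]
        if accepted:
            return accepted[-1].best_accuracy
        return self.initial.mean_accuracy


Evaluator = Callable[[tuple], SubsetEvaluation]


def backward_eliminate(
    feature_names: Sequence[str],
    evaluator: Evaluator,
    config: SelectionConfig,
) -> SelectionResult:
    """Backward variable elimination driven by ``evaluator``.

    ``evaluator`` maps a tuple of feature names (a subset, kept in original
    order) to a :class:`SubsetEvaluation`; the default HD evaluator is
    :class:`HDSubsetEvaluator`, but any callable (e.g. a test stub) works.
    """
    feature_names = list(feature_names)
    if len(feature_names) == 0:
        raise ValueError("need at least one feature")
    T = config.accuracy_threshold
    u = config.accuracy_uncertainty

    current = list(feature_names)
    bucket: list[str] = []
    trace: list[IterationRecord] = []
    models_evaluated = 1

    init_eval = evaluator(tuple(current))
    initial = CandidateRecord(
        excluded_feature=None,
        mean_accuracy=init_eval.mean_accuracy,
        fold_accuracies=list(init_eval.fold_accuracies),
        mean_retrain_iterations=init_eval.mean_retrain_iterations,
    )
    best_features = list(current)
    best_accuracy = init_eval.mean_accuracy

    if init_eval.mean_accuracy < T:
        return SelectionResult(
            feature_names=feature_names,
            selected=current,
            excluded=bucket,
            initial=initial,
            trace=trace,
            best_features=best_features,
            best_accuracy=best_accuracy,
            models_evaluated=models_evaluated,
            terminated_reason="initial_model_below_threshold",
        )

    prev_best = init_eval.mean_accuracy
    reason = "features_exhausted"
    iteration = 0
    while current:
        iteration += 1
        candidates = []
        for f in current:
            subset = tuple(x for x in current if x != f)
            ev = evaluator(subset)
            models_evaluated += 1
            candidates.append(
                CandidateRecord(
                    excluded_feature=f,
                    mean_accuracy=ev.mean_accuracy,
                    fold_accuracies=list(ev.fold_accuracies),
                    mean_retrain_iterations=ev.mean_retrain_iterations,
                )
            )
        kept = [c for c in candidates if c.mean_accuracy >= T]
        if not kept:
            trace.append(
                IterationRecord(
                    iteration=iteration,
                    candidates=candidates,
                    best_accuracy=max(c.mean_accuracy for c in candidates),
                    band_cutoff=None,
                    removed_features=[],
                    accepted=False,
                )
            )
            reason = "below_threshold"
            break
        best = max(c.mean_accuracy for c in kept)
        if best < acceptance_cutoff(prev_best, u):
            # Decrease beyond the uncertainty band: reject the iteration.
            trace.append(
                IterationRecord(
                    iteration=iteration,
                    candidates=candidates,
                    best_accuracy=best,
                    band_cutoff=None,
                    removed_features=[],
                    accepted=False,
                )
            )
            reason = "accuracy_decreased"
            break
        cutoff = acceptance_cutoff(best, u)
        removed = sorted(
            (c for c in kept if c.mean_accuracy >= cutoff),
            key=lambda c: (-c.mean_accuracy, current.index(c.excluded_feature)),
        )
        removed_names = [c.excluded_feature for c in removed]
        trace.append(
            IterationRecord(
                iteration=iteration,
                candidates=candidates,
                best_accuracy=best,
                band_cutoff=cutoff,
                removed_features=removed_names,
                accepted=True,
            )
        )
        if best > best_accuracy:
            best_accuracy = best
            winner = removed[0].excluded_feature
            best_features = [f for f in current if f != winner]
        bucket.extend(removed_names)
        current = [f for f in current if f not in set(removed_names)]
        prev_best = best

    return SelectionResult(
        feature_names=feature_names,
        selected=current,
        excluded=bucket,
        initial=initial,
        trace=trace,
        best_features=best_features,
        best_accuracy=best_accuracy,
        models_evaluated=models_evaluated,
        terminated_reason=reason,
    )


def forward_select_order(
    feature_names: Sequence[str],
    evaluator: Evaluator,
    config: SelectionConfig,
    max_features: int | None = None,
) -> list:
    """Greedy forward counterpart: add the single best feature per step.

    Provided for completeness; the backward wrapper is the primary surface.
    Returns feature names in order of addition, stopping when accuracy stops
    improving or ``max_features`` is reached.
    """
    remaining = list(feature_names)
    chosen: list[str] = []
    best_so_far = -np.inf
    limit = max_features or len(remaining)
    while remaining and len(chosen) < limit:
        scored = [
            (evaluator(tuple(chosen + [f])).mean_accuracy, i, f)
            for i, f in enumerate(remaining)
        ]
        acc, _, f = max(scored, key=lambda t: (t[0], -t[1]))
        if acc <= best_so_far:
            break
        chosen.append(f)
        remaining.remove(f)
        best_so_far = acc
    return chosen


@dataclass
class FrontierModel:
    features: tuple
    accuracy: float
    iteration: int  # 0 = the initial full-set model


def _enumerate_models(result: SelectionResult):
    """Yield (features, accuracy, iteration, order) for every evaluated model."""
    order = 0
    yield tuple(result.feature_names), result.initial.mean_accuracy, 0, order
    base = list(result.feature_names)
    for record in result.trace:
        for cand in record.candidates:
            order += 1
            subset = tuple(f for f in base if f != cand.excluded_feature)
            yield subset, cand.mean_accuracy, record.iteration, order
        if record.accepted:
            removed = set(record.removed_features)
            base = [f for f in base if f not in removed]


def suboptimal_frontier(
    result: SelectionResult, min_accuracy: float = 70.0
) -> FrontierModel | None:
    """Fewest-feature evaluated model with accuracy strictly above the floor.

    Ties on size are broken by higher accuracy, then by earliest evaluation.
    Returns None when no model qualifies.
    """
    best = None
    best_key = None
    for features, accuracy, iteration, order in _enumerate_models(result):
        if accuracy > min_accuracy:
            key = (len(features), -accuracy, order)
            if best_key is None or key < best_key:
                best_key = key
                best = FrontierModel(features=features, accuracy=accuracy, iteration=iteration)
    return best


class HDSubsetEvaluator:
    """Cross-validated HD accuracy of feature subsets, with shared folds.

    The fold plan, level vectors, and per-fold quantization are fixed once
    per run so candidate accuracies are directly comparable.  Encodings are
    additive over features, so a candidate's encodings are derived from a
    cached neighbouring subset by adding/subtracting single-feature
    contributions instead of re-encoding from scratch.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        config: SelectionConfig,
        fold_plan=None,
        levels=None,
    ):
        self.dataset = dataset
        self.config = config
        self.levels = levels if levels is not None else generate_levels(
            config.dimension, config.n_levels, config.seed
        )
        self.fold_plan = fold_plan if fold_plan is not None else make_folds(
            dataset.labels, config.folds, config.seed
        )
        self.class_labels = dataset.class_labels
        self._index = {name: i for i, name in enumerate(dataset.feature_names)}
        self._folds = []
        for train_idx, test_idx in self.fold_plan.splits(dataset.n_samples):
            scheme = QuantizationScheme.from_values(
                dataset.values[train_idx], self.levels.n_levels
            )
            level_idx = scheme.indices(dataset.values)
            self._folds.append(
                {"train": train_idx, "test": test_idx, "level_idx": level_idx}
            )
        # Subset-encoding cache: the full set (anchor) plus the most recent
        # request; any subset is reachable from one of them by a small
        # symmetric difference.
        self._full_key = frozenset(dataset.feature_names)
        self._cache: dict[frozenset, list[np.ndarray]] = {}
        self._recent_key: frozenset | None = None

    def _full_encodings(self) -> list[np.ndarray]:
        if self._full_key not in self._cache:
            encs = []
            for fold in self._folds:
                enc = np.zeros(
                    (self.dataset.n_samples, self.levels.d), dtype=np.int32
                )
                for name, f in self._index.items():
                    enc += feature_contributions(
                        fold["level_idx"][:, f], f, self.levels
                    )
                encs.append(enc)
            self._cache[self._full_key] = encs
        return self._cache[self._full_key]

    def _encodings(self, key: frozenset) -> list[np.ndarray]:
        if key in self._cache:
            return self._cache[key]
        self._full_encodings()
        base_key = min(
            self._cache, key=lambda k: len(k.symmetric_difference(key))
        )
        to_remove = base_key - key
        to_add = key - base_key
        encs = []
        for fold, base in zip(self._folds, self._cache[base_key]):
            enc = base.copy()
            for name in to_remove:
                f = self._index[name]
                enc -= feature_contributions(fold["level_idx"][:, f], f, self.levels)
            for name in to_add:
                f = self._index[name]
                enc += feature_contributions(fold["level_idx"][:, f], f, self.levels)
            encs.append(enc)
        if self._recent_key is not None and self._recent_key != self._full_key:
            self._cache.pop(self._recent_key, None)
        self._cache[key] = encs
        self._recent_key = key
        return encs

    def __call__(self, subset: tuple) -> SubsetEvaluation:
        unknown = [f for f in subset if f not in self._index]
        if unknown:
            raise KeyError(f"unknown features: {unknown}")
        encs = self._encodings(frozenset(subset))
        accs, iters, conserved = [], [], True
        for fold, enc in zip(self._folds, encs):
            train, test = fold["train"], fold["test"]
            model = fit_classes(
                enc[train], self.dataset.labels[train], self.class_labels
            )
            res = retrain(
                model,
                enc[train],
                self.dataset.labels[train],
                self.config.retrain_iterations,
            )
            conserved = conserved and res.conserved
            report = evaluate(res.model, enc[test], self.dataset.labels[test])
            accs.append(100.0 * report.accuracy)
            iters.append(res.iterations_used)
        return SubsetEvaluation(
            mean_accuracy=float(np.mean(accs)),
            fold_accuracies=accs,
            mean_retrain_iterations=float(np.mean(iters)),
            conserved=conserved,
        )


def write_trace_jsonl(result: SelectionResult, path) -> None:
    """One JSON line for the initial model, then one per iteration record."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"iteration": 0, "initial": asdict(result.initial)},
                            sort_keys=True) + "\n")
        for record in result.trace:
            fh.write(json.dumps(asdict(record), sort_keys=True) + "\n")
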