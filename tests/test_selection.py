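import numpy as np
import pytest

from hdselect.selection import (
    HDSubsetEvaluator,
    SelectionConfig,
    SubsetEvaluation,
    acceptance_cutoff,
    backward_eliminate,
    display_percent,
    forward_select_order,
    suboptimal_frontier,
    write_trace_jsonl,
)
from hdselect.synthetic import make_binary_dataset


class TestAcceptanceCutoff:
    @pytest.mark.parametrize(
        "best,u,exact,displayed",
        [(93.0, 5.0, 88.35, 88), (90.0, 5.0, 85.5, 85)],
    )
    def test_relative_band_with_floored_display(self, best, u, exact, displayed):
        cutoff = acceptance_cutoff(best, u)
        assert cutoff == pytest.approx(exact)
        assert display_percent(cutoff) == displayed

    def test_zero_uncertainty_is_identity(self):
        for x in (0.0, 33.3, 100.0):
            assert acceptance_cutoff(x, 0.0) == x


class TestWalkthrough:
    def test_five_feature_walkthrough(self, walkthrough_evaluator, walkthrough_config):
        res = backward_eliminate(
            ["F1", "F2", "F3", "F4", "F5"], walkthrough_evaluator, walkthrough_config
        )
        assert res.selected == ["F1", "F4"]
        assert res.excluded == ["F2", "F3", "F5"]
        assert res.terminated_reason == "accuracy_decreased"
        assert res.final_accepted_best_accuracy() == 90.0
        assert [r.removed_features for r in res.trace] == [["F2", "F3"], ["F5"], []]
        assert res.models_evaluated == 11

    def test_frontier_picks_smallest_model_above_floor(
        self, walkthrough_evaluator, walkthrough_config
    ):
        res = backward_eliminate(
            ["F1", "F2", "F3", "F4", "F5"], walkthrough_evaluator, walkthrough_config
        )
        frontier = suboptimal_frontier(res, 70.0)
        assert frontier.features == ("F4",)
        assert frontier.accuracy == 75.0
        assert suboptimal_frontier(res, 100.0) is None

    def test_trace_jsonl_round_trip(
        self, walkthrough_evaluator, walkthrough_config, tmp_path
    ):
        import json

        res = backward_eliminate(
            ["F1", "F2", "F3", "F4", "F5"], walkthrough_evaluator, walkthrough_config
        )
        path = tmp_path / "trace.jsonl"
        write_trace_jsonl(res, path)
        lines = [json.loads(line) for line in path.read_text().splitlines()]
        assert lines[0]["initial"]["mean_accuracy"] == 80.0
        assert len(lines) == 1 + len(res.trace)


def constant_evaluator(acc):
    def ev(subset):
        return SubsetEvaluation(acc, [acc], 0.0)

    return ev


class TestTermination:
    def test_initial_model_below_threshold_keeps_all_features(self):
        cfg = SelectionConfig(accuracy_threshold=60.0, seed=0)
        res = backward_eliminate(["a", "b", "c"], constant_evaluator(40.0), cfg)
        assert res.terminated_reason == "initial_model_below_threshold"
        assert res.selected == ["a", "b", "c"]
        assert res.trace == []
        assert res.models_evaluated == 1

    def test_constant_accuracy_exhausts_features(self):
        # Every candidate ties the best, so the band removes everything.
        cfg = SelectionConfig(accuracy_threshold=60.0, accuracy_uncertainty=1.0, seed=0)
        res = backward_eliminate(["a", "b", "c"], constant_evaluator(80.0), cfg)
        assert res.terminated_reason == "features_exhausted"
        assert res.selected == []
        assert set(res.excluded) == {"a", "b", "c"}

    def test_single_feature_dataset(self):
        cfg = SelectionConfig(accuracy_threshold=60.0, seed=0)
        res = backward_eliminate(["only"], constant_evaluator(80.0), cfg)
        assert res.terminated_reason in {"features_exhausted", "accuracy_decreased"}
        assert len(res.trace) == 1

    def test_below_threshold_stops_without_removal(self):
        accs = {("a", "b"): 80.0, ("b",): 50.0, ("a",): 55.0}

        def ev(subset):
            acc = accs[tuple(subset)]
            return SubsetEvaluation(acc, [acc], 0.0)

        cfg = SelectionConfig(accuracy_threshold=60.0, seed=0)
        res = backward_eliminate(["a", "b"], ev, cfg)
        assert res.terminated_reason == "below_threshold"
        assert res.selected == ["a", "b"]


class TestZeroUncertaintyDegeneratesToSingleStep:
    def test_one_removal_per_iteration_with_distinct_accuracies(self):
        rng = np.random.default_rng(0)
        scores = {}

        def ev(subset):
            key = frozenset(subset)
            if key not in scores:
                scores[key] = 90.0 + rng.uniform(0, 5)  # distinct, never decreasing much
            acc = scores[key]
            return SubsetEvaluation(acc, [acc], 0.0)

        cfg = SelectionConfig(
            accuracy_threshold=0.0, accuracy_uncertainty=0.0, seed=0
        )
        res = backward_eliminate(list("abcdef"), ev, cfg)
        for record in res.trace:
            if record.accepted:
                assert len(record.removed_features) == 1

    def test_invariants_on_trace(self, walkthrough_evaluator, walkthrough_config):
        res = backward_eliminate(
            ["F1", "F2", "F3", "F4", "F5"], walkthrough_evaluator, walkthrough_config
        )
        # selected and excluded partition the initial features
        assert sorted(res.selected + res.excluded) == sorted(res.feature_names)
        assert not set(res.selected) & set(res.excluded)
        # every removed feature's model met both the threshold and the band
        for record in res.trace:
            if not record.accepted:
                continue
            by_name = {c.excluded_feature: c for c in record.candidates}
            for f in record.removed_features:
                assert by_name[f].mean_accuracy >= walkthrough_config.accuracy_threshold
                assert by_name[f].mean_accuracy >= record.band_cutoff
        # model count matches the trace arithmetic
        assert res.models_evaluated == 1 + sum(len(r.candidates) for r in res.trace)


@pytest.fixture(scope="module")
def small_run():
    dataset, truth = make_binary_dataset(
        n_case=30, n_control=30, n_features=10, n_informative=3,
        p_case=0.9, p_control=0.1, seed=5,
    )
    cfg = SelectionConfig(
        accuracy_threshold=60.0, accuracy_uncertainty=1.0,
        dimension=2048, n_levels=2, retrain_iterations=5, folds=3, seed=5,
    )
    evaluator = HDSubsetEvaluator(dataset, cfg)
    return dataset, truth, cfg, evaluator


class TestHDEvaluatorIntegration:
    def test_incremental_encodings_match_fresh_evaluator(self, small_run):
        # The cached/incremental subset encodings must agree exactly with a
        # fresh evaluator that encodes the same subset from scratch.
        dataset, truth, cfg, evaluator = small_run
        subset = tuple(dataset.feature_names[i] for i in (0, 2, 3, 7, 9))
        warm = evaluator(tuple(dataset.feature_names))  # populate cache
        incremental = evaluator(subset)
        fresh = HDSubsetEvaluator(dataset, cfg)(subset)
        assert incremental.fold_accuracies == fresh.fold_accuracies

    def test_planted_features_survive_selection(self, small_run):
        dataset, truth, cfg, evaluator = small_run
        res = backward_eliminate(dataset.feature_names, evaluator, cfg)
        assert set(truth.informative_features) & set(res.selected)
        assert res.models_evaluated == 1 + sum(len(r.candidates) for r in res.trace)

    def test_same_seed_same_result(self, small_run):
        dataset, truth, cfg, _ = small_run
        r1 = backward_eliminate(dataset.feature_names, HDSubsetEvaluator(dataset, cfg), cfg)
        r2 = backward_eliminate(dataset.feature_names, HDSubsetEvaluator(dataset, cfg), cfg)
        assert r1.selected == r2.selected
        assert [c.mean_accuracy for r in r1.trace for c in r.candidates] == [
            c.mean_accuracy for r in r2.trace for c in r.candidates
        ]


class TestForwardSelection:
    def test_adds_best_features_in_order(self):
        gains = {"a": 70.0, "b": 90.0, "c": 80.0}

        def ev(subset):
            acc = max(gains[f] for f in subset)
            return SubsetEvaluation(acc, [acc], 0.0)

        cfg = SelectionConfig(seed=0)
        order = forward_select_order(["a", "b", "c"], ev, cfg)
        assert order[0] == "b"
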