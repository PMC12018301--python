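import numpy as np
import pandas as pd
import pytest

from hdselect.profiles import UNCLASSIFIED, AbundanceTable
from hdselect.selection import SelectionConfig, SubsetEvaluation
from hdselect.synthetic import make_binary_dataset


# Accuracies of the five-feature backward-elimination walkthrough: the full
# model, all leave-one-out candidates, and the candidates of the two
# subsequent iterations.  Keys are the candidate feature subsets.
FIG_WALKTHROUGH = {
    frozenset({"F1", "F2", "F3", "F4", "F5"}): 80.0,
    frozenset({"F2", "F3", "F4", "F5"}): 75.0,  # drop F1
    frozenset({"F1", "F3", "F4", "F5"}): 93.0,  # drop F2
    frozenset({"F1", "F2", "F4", "F5"}): 91.0,  # drop F3
    frozenset({"F1", "F2", "F3", "F5"}): 72.0,  # drop F4
    frozenset({"F1", "F2", "F3", "F4"}): 68.0,  # drop F5
    frozenset({"F4", "F5"}): 65.0,
    frozenset({"F1", "F5"}): 60.0,
    frozenset({"F1", "F4"}): 90.0,
    frozenset({"F4"}): 75.0,
    frozenset({"F1"}): 72.0,
}


@pytest.fixture
def walkthrough_evaluator():
    def stub(subset):
        acc = FIG_WALKTHROUGH[frozenset(subset)]
        return SubsetEvaluation(
            mean_accuracy=acc, fold_accuracies=[acc], mean_retrain_iterations=0.0
        )

    return stub


@pytest.fixture
def walkthrough_config():
    return SelectionConfig(accuracy_threshold=70.0, accuracy_uncertainty=5.0, seed=0)


@pytest.fixture(scope="session")
def planted_dataset():
    """Planted binary dataset: 100+100 samples, 5/50 informative at 0.85/0.15."""
    return make_binary_dataset(
        n_case=100, n_control=100, n_features=50, n_informative=5,
        p_case=0.85, p_control=0.15, p_background=0.30, seed=42,
    )


def _table(rows: dict, samples: list[str], study=None) -> AbundanceTable:
    return AbundanceTable(
        pd.DataFrame(rows, index=samples).T.astype(float), study=study
    )


SP1 = "k__Bacteria|p__Firmicutes|g__Gemella|s__Gemella_morbillorum"
SP2 = "k__Bacteria|p__Firmicutes|g__Parvimonas|s__Parvimonas_micra"
SP3 = "k__Bacteria|p__Firmicutes|g__Blautia|s__Blautia_sp"


@pytest.fixture
def three_study_toy():
    """Three tiny cohorts; SP3 is detected in studies A and B but not C."""
    a = _table(
        {SP1: [10.0, 5.0], SP2: [20.0, 0.0], SP3: [5.0, 15.0], UNCLASSIFIED: [65.0, 80.0]},
        ["a1", "a2"], study="A",
    )
    b = _table(
        {SP1: [8.0], SP2: [12.0], SP3: [0.0], UNCLASSIFIED: [80.0]},
        ["b1"], study="B",
    )
    c = _table(
        {SP1: [30.0, 1.0], SP2: [10.0, 2.0], UNCLASSIFIED: [60.0, 97.0]},
        ["c1", "c2"], study="C",
    )
    return [a, b, c]


@pytest.fixture
def toy_metadata():
    md = pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "b1", "c1", "c2"],
            "class": ["CRC", "control", "CRC", "control", "CRC"],
            "sex": ["female", "male", "male", "female", "male"],
            "age": [60, 70, 65, 66, 40],
            "study": ["A", "A", "B", "C", "C"],
        }
    )
    return md.set_index("sample_id", drop=False)
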