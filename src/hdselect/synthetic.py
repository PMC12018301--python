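"""Seeded generators for planted-signal datasets.

The generators emulate the statistical structure of binarized species
tables in a case/control design: most features are uninformative background
presence/absence noise, while a small set of planted ("informative")
features differ in per-class prevalence -- the regime in which real
discriminative species operate (e.g. a pathogen-associated species detected
in ~half the cases but under 10% of controls).  Defaults plant a clearly
learnable signal (presence probability 0.85 in cases vs 0.15 in controls)
in 5 of 50 features at 100 + 100 samples.

The relative-abundance generator layers positive abundances (gamma draws)
on the same presence pattern and pads each sample with an ``unclassified``
remainder so species + unclassified sum to exactly 100.

Everything is a pure function of its arguments, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import LabeledDataset
from .profiles import UNCLASSIFIED, AbundanceTable

__all__ = ["SyntheticTruth", "make_binary_dataset", "make_ra_dataset"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a planted dataset."""

    informative_features: tuple
    p_case: float
    p_control: float
    p_background: float
    n_case: int
    n_control: int
    seed: int


def _validate(n_case, n_control, n_features, n_informative, probs):
    if n_case < 1 or n_control < 1:
        raise ValueError("class sizes must be >= 1")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not 0 <= n_informative <= n_features:
        raise ValueError("n_informative must be in [0, n_features]")
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")


def make_binary_dataset(
    n_case: int = 100,
    n_control: int = 100,
    n_features: int = 50,
    n_informative: int = 5,
    p_case: float = 0.85,
    p_control: float = 0.15,
    p_background: float = 0.30,
    seed: int = 0,
    case_label: str = "case",
    control_label: str = "control",
) -> tuple[LabeledDataset, SyntheticTruth]:
    """Presence/absence matrix with ``n_informative`` planted features.

    Informative features are 1 with probability ``p_case`` in case samples
    and ``p_control`` in controls; all other features are 1 with
    ``p_background`` everywhere.  Draws are independent.
    """
    _validate(n_case, n_control, n_features, n_informative, (p_case, p_control, p_background))
    rng = np.random.default_rng(seed)
    feature_names = [f"species_{i:04d}" for i in range(n_features)]
    informative = np.sort(rng.choice(n_features, size=n_informative, replace=False))
    n = n_case + n_control
    probs = np.full((n, n_features), p_background, dtype=np.float64)
    probs[:n_case, informative] = p_case
    probs[n_case:, informative] = p_control
    values = (rng.random((n, n_features)) < probs).astype(np.float64)
    labels = np.asarray([case_label] * n_case + [control_label] * n_control, dtype=object)
    sample_ids = [f"sample_{i:04d}" for i in range(n)]
    dataset = LabeledDataset(
        feature_names=feature_names,
        values=values,
        labels=labels,
        sample_ids=sample_ids,
    )
    truth = SyntheticTruth(
        informative_features=tuple(feature_names[i] for i in informative),
        p_case=p_case,
        p_control=p_control,
        p_background=p_background,
        n_case=n_case,
        n_control=n_control,
        seed=int(seed),
    )
    return dataset, truth


def make_ra_dataset(
    n_case: int = 100,
    n_control: int = 100,
    n_features: int = 50,
    n_informative: int = 5,
    p_case: float = 0.85,
    p_control: float = 0.15,
    p_background: float = 0.30,
    concentration: float = 1.0,
    seed: int = 0,
    case_label: str = "case",
    control_label: str = "control",
) -> tuple[AbundanceTable, pd.DataFrame, SyntheticTruth]:
    """Relative-abundance table with the same planted presence structure.

    Present species receive gamma(``concentration``) weights scaled so the
    profiled species of each sample account for a fraction of the total
    (the rest goes to ``unclassified``); every per-sample column sums to
    exactly 100.  Returns (table, metadata, truth); ``binarize`` of the table
    recovers the underlying presence pattern.
    """
    dataset, truth = make_binary_dataset(
        n_case,
        n_control,
        n_features,
        n_informative,
        p_case,
        p_control,
        p_background,
        seed,
        case_label,
        control_label,
    )
    # Lineage-style names so the table round-trips through the species-level
    # profile reader.
    lineages = [
        f"k__Bacteria|p__Synthetica|g__Genus_{i:04d}|s__Species_{i:04d}"
        for i in range(n_features)
    ]
    informative_lineages = tuple(
        lineages[dataset.feature_names.index(f)] for f in truth.informative_features
    )
    truth = SyntheticTruth(
        informative_features=informative_lineages,
        p_case=truth.p_case,
        p_control=truth.p_control,
        p_background=truth.p_background,
        n_case=truth.n_case,
        n_control=truth.n_control,
        seed=truth.seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    present = dataset.values > 0
    weights = rng.gamma(concentration, size=present.shape) * present
    # Species fraction of each sample's profile; the rest is unclassified.
    species_fraction = rng.uniform(0.6, 0.95, size=present.shape[0])
    ra = np.zeros_like(weights)
    for i in range(present.shape[0]):
        total = weights[i].sum()
        if total > 0:
            ra[i] = weights[i] / total * 100.0 * species_fraction[i]
    unclassified = 100.0 - ra.sum(axis=1)
    data = pd.DataFrame(ra.T, index=lineages, columns=dataset.sample_ids)
    data.loc[UNCLASSIFIED] = unclassified
    table = AbundanceTable(data)
    ages = rng.integers(30, 85, size=present.shape[0])
    sexes = rng.choice(["female", "male"], size=present.shape[0])
    metadata = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "class": dataset.labels,
            "sex": sexes,
            "age": ages,
            "study": "synthetic",
        }
    ).set_index("sample_id", drop=False)
    return table, metadata, truth
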