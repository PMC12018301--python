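"""Reading, merging, filtering, binarizing, and stratifying microbial profiles.

Input tables follow the merged MetaPhlAn dialect: a TSV whose first column
holds rank-prefixed, pipe-separated taxonomy lineages (k__...|p__...|s__...),
one column per sample, and relative abundances (RA) in percent.  Only
species-level rows are analyzed; every sample carries a reserved
``unclassified`` row holding the abundance not attributed to a profiled
species.  All row-dropping operations reassign the dropped RA to
``unclassified``, so the per-sample total abundance is conserved exactly --
the filters change how the abundance is labelled, never how much there is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import LabeledDataset

__all__ = [
    "UNCLASSIFIED",
    "AbundanceTable",
    "read_profiles",
    "write_profiles",
    "read_metadata",
    "merge_intersect",
    "filter_species",
    "binarize",
    "stratify",
    "to_labeled_dataset",
    "read_feature_table",
    "write_feature_table",
]

UNCLASSIFIED = "unclassified"


@dataclass
class AbundanceTable:
    """Species x samples relative abundances (percent), plus ``unclassified``.

    ``data`` is indexed by taxonomy lineage (or the reserved ``unclassified``
    row); columns are sample ids.  ``study`` optionally names the cohort the
    table came from, used when merging multi-study inputs.
    """

    data: pd.DataFrame
    study: str | None = None

    def __post_init__(self):
        self.data = self.data.astype(np.float64)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate row identifiers: {dupes[:5]}")
        if UNCLASSIFIED not in self.data.index:
            self.data.loc[UNCLASSIFIED] = 0.0
        if (self.data.values < 0).any():
            raise ValueError("relative abundances must be non-negative")
        totals = self.data.sum(axis=0)
        if (totals > 100.0 + 1e-6).any():
            bad = totals[totals > 100.0 + 1e-6].index.tolist()
            raise ValueError(f"per-sample abundance exceeds 100%: {bad[:5]}")

    @property
    def species(self) -> list[str]:
        return [r for r in self.data.index if r != UNCLASSIFIED]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), study=self.study)


def _is_species_lineage(lineage: str) -> bool:
    """True for species-level lineages: an s__ rank with no strain suffix."""
    last = lineage.split("|")[-1]
    return last.startswith("s__")


def read_profiles(path: str | Path, study: str | None = None) -> AbundanceTable:
    """Read a merged MetaPhlAn-style TSV, keeping species rows + unclassified.

    Rows at other taxonomic ranks (kingdom through genus, and strain-level
    t__ rows) are dropped: the analysis is species-level only.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as err:
        raise ValueError(f"cannot parse {path}: {err}") from err
    if raw.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    for col in raw.columns:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            bad = raw[pd.to_numeric(raw[col], errors="coerce").isna()].index
            raise ValueError(
                f"{path}: non-numeric abundance in column {col!r}, "
                f"row {bad[0] if len(bad) else '?'}"
            )
    keep = [
        r
        for r in raw.index
        if r == UNCLASSIFIED or _is_species_lineage(str(r))
    ]
    return AbundanceTable(raw.loc[keep], study=study)


def write_profiles(table: AbundanceTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, class, sex, age, study).

    Adenoma samples are excluded with a warning: the case/control design
    covers CRC vs control only.
    """
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "class"}
    missing = required - set(md.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    adenoma = md["class"].astype(str).str.lower() == "adenoma"
    if adenoma.any():
        warnings.warn(
            f"dropping {int(adenoma.sum())} adenoma samples from the metadata",
            UserWarning,
        )
        md = md[~adenoma]
    if "age" in md.columns and (pd.to_numeric(md["age"], errors="coerce") < 0).any():
        raise ValueError("ages must be non-negative")
    return md.set_index("sample_id", drop=False)


def _reassign_to_unclassified(data: pd.DataFrame, drop_rows: list[str]) -> pd.DataFrame:
    """Drop species rows, adding their per-sample RA to ``unclassified``."""
    if not drop_rows:
        return data
    out = data.drop(index=drop_rows)
    out.loc[UNCLASSIFIED] = out.loc[UNCLASSIFIED] + data.loc[drop_rows].sum(axis=0)
    return out


def merge_intersect(tables: list[AbundanceTable]) -> AbundanceTable:
    """Merge multi-study tables, keeping species detected in *every* study.

    A species counts as detected in a study when its RA is > 0 in at least
    one of that study's samples.  Species failing the intersection are
    removed from the species rows of each study and their abundance added to
    that sample's ``unclassified`` row, so per-sample totals are conserved.
    """
    if len(tables) == 0:
        raise ValueError("need at least one table")
    all_samples: list[str] = []
    for t in tables:
        all_samples.extend(t.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("sample ids must be disjoint across studies")
    detected_sets = []
    for t in tables:
        data = t.data
        detected = {
            s for s in t.species if (data.loc[s] > 0).any()
        }
        detected_sets.append(detected)
    shared = set.intersection(*detected_sets)
    # Preserve first-appearance order across tables.
    ordered: list[str] = []
    for t in tables:
        for s in t.species:
            if s in shared and s not in ordered:
                ordered.append(s)
    pieces = []
    for t in tables:
        drop = [s for s in t.species if s not in shared]
        reduced = _reassign_to_unclassified(t.data, drop)
        reduced = reduced.reindex(ordered + [UNCLASSIFIED], fill_value=0.0)
        pieces.append(reduced)
    merged = pd.concat(pieces, axis=1)
    return AbundanceTable(merged)


def filter_species(
    table: AbundanceTable,
    ra_threshold: float = 1.0,
    prevalence_threshold: float = 5.0,
) -> AbundanceTable:
    """Drop very-low-abundance then low-prevalence species (RA conserved).

    A species is low-abundance when its *maximum* RA across samples is below
    ``ra_threshold`` percent, and low-prevalence when it is detected
    (RA > 0) in fewer than ``prevalence_threshold`` percent of samples.
    Dropped abundance moves to ``unclassified``.
    """
    if not (0.0 <= ra_threshold <= 100.0 and 0.0 <= prevalence_threshold <= 100.0):
        raise ValueError("thresholds must be in [0, 100]")
    data = table.data.copy()
    species = [r for r in data.index if r != UNCLASSIFIED]
    low_ra = [s for s in species if data.loc[s].max() < ra_threshold]
    data = _reassign_to_unclassified(data, low_ra)
    species = [r for r in data.index if r != UNCLASSIFIED]
    n = data.shape[1]
    low_prev = [
        s
        for s in species
        if 100.0 * (data.loc[s] > 0).sum() / n < prevalence_threshold
    ]
    data = _reassign_to_unclassified(data, low_prev)
    return AbundanceTable(data, study=table.study)


def binarize(table: AbundanceTable) -> pd.DataFrame:
    """Presence/absence matrix: 1 where RA > 0, else 0; unclassified dropped.

    Returns a species x samples integer DataFrame (idempotent on already
    binary input).
    """
    species = table.species
    return (table.data.loc[species] > 0).astype(np.int64)


def stratify(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    by: str,
) -> dict[str, AbundanceTable]:
    """Split samples into strata by ``sex`` ({male, female}) or ``age``.

    Age strata follow the 65-year threshold: adult = age <= 65, senior =
    age > 65.  Samples with the key missing are excluded with a warning;
    the feature (row) set is unchanged.
    """
    if by not in {"sex", "age"}:
        raise ValueError(f"unknown stratification key: {by!r}")
    if by not in metadata.columns:
        raise ValueError(f"metadata has no {by!r} column")
    md = metadata.reindex([s for s in table.sample_ids])
    missing = md.index[md[by].isna() | ~md.index.isin(metadata.index)].tolist()
    if by == "sex":
        missing = sorted(
            set(missing)
            | {
                s
                for s in md.index
                if str(md.loc[s, "sex"]).lower() not in {"male", "female"}
            }
        )
    if missing:
        warnings.warn(
            f"excluding {len(missing)} samples with missing/unknown {by!r}",
            UserWarning,
        )
    usable = [s for s in table.sample_ids if s not in set(missing)]
    md = md.loc[usable]
    strata: dict[str, list[str]] = {}
    if by == "sex":
        for name in ("male", "female"):
            strata[name] = [s for s in usable if str(md.loc[s, "sex"]).lower() == name]
    else:
        ages = pd.to_numeric(md["age"])
        strata["adult"] = [s for s in usable if ages[s] <= 65]
        strata["senior"] = [s for s in usable if ages[s] > 65]
    return {
        name: AbundanceTable(table.data[samples].copy(), study=table.study)
        for name, samples in strata.items()
        if samples
    }


def to_labeled_dataset(
    matrix: pd.DataFrame, metadata: pd.DataFrame, label_column: str = "class"
) -> LabeledDataset:
    """Turn a species x samples matrix + metadata into a LabeledDataset."""
    samples = [s for s in matrix.columns if s in metadata.index]
    dropped = set(matrix.columns) - set(samples)
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} samples without metadata", UserWarning
        )
    labels = metadata.loc[samples, label_column].astype(str).to_numpy(dtype=object)
    return LabeledDataset(
        feature_names=[str(r) for r in matrix.index],
        values=matrix[samples].to_numpy(dtype=np.float64).T,
        labels=labels,
        sample_ids=list(samples),
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Generic features x samples numeric TSV (first column = feature name)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature names")
    return df.astype(np.float64)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")
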