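"""Quantization of scalar features to level vectors and sample encoding.

A sample (one row of a numeric feature table) is encoded into a single
integer hypervector by (i) quantizing each feature value to one of L level
vectors, (ii) rotating that level vector by the feature's position so the
representation keeps track of *which* feature carried the value, and
(iii) bundling the rotated vectors.  Because bundling is a plain sum, the
encoding is additive over features: the encoding of a feature subset equals
the full encoding minus the rotated level vectors of the removed features
(exact integer equality).  The backward-elimination wrapper exploits this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .vsa import LevelEncoding

__all__ = [
    "QuantizationScheme",
    "LabeledDataset",
    "value_to_level",
    "encode_sample",
    "encode_matrix",
    "feature_contributions",
]


@dataclass(frozen=True)
class QuantizationScheme:
    """Uniform, right-closed quantization of [value_min, value_max] into L bins.

    value_min maps to level 0 and value_max to level L-1; with range [0, 100]
    and L = 100 every value in (0, 1] shares level 0, so nearby magnitudes
    deliberately collapse onto the same level vector.  Values outside the
    range (e.g. at test time, when the range was fitted on training data
    only) are clamped with a warning.
    """

    value_min: float
    value_max: float
    n_levels: int

    def __post_init__(self):
        if not (np.isfinite(self.value_min) and np.isfinite(self.value_max)):
            raise ValueError("quantization range must be finite")
        if self.value_min > self.value_max:
            raise ValueError("value_min must be <= value_max")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")

    @classmethod
    def from_values(cls, values, n_levels: int) -> "QuantizationScheme":
        """Fit the global range over a (training) value table."""
        a = np.asarray(values, dtype=np.float64)
        if a.size == 0:
            raise ValueError("cannot fit a quantization scheme on no values")
        if not np.all(np.isfinite(a)):
            raise ValueError("values must be finite")
        return cls(float(a.min()), float(a.max()), int(n_levels))

    def indices(self, values) -> np.ndarray:
        """Vectorized level index: 0 for x <= min, else ceil((x-min)/w) - 1."""
        x = np.asarray(values, dtype=np.float64)
        if not np.all(np.isfinite(x)):
            raise ValueError("cannot quantize non-finite values")
        if np.any(x < self.value_min) or np.any(x > self.value_max):
            warnings.warn(
                "values outside the quantization range were clamped", RuntimeWarning
            )
            x = np.clip(x, self.value_min, self.value_max)
        if self.value_min == self.value_max:
            return np.zeros(x.shape, dtype=np.int64)
        w = (self.value_max - self.value_min) / self.n_levels
        idx = np.ceil((x - self.value_min) / w).astype(np.int64) - 1
        idx[x <= self.value_min] = 0
        return np.clip(idx, 0, self.n_levels - 1)


def value_to_level(x: float, scheme: QuantizationScheme) -> int:
    """Level index of a single value under ``scheme`` (right-closed bins)."""
    return int(scheme.indices(np.asarray([x]))[0])


@dataclass
class LabeledDataset:
    """Samples x features numeric table with one class label per sample."""

    feature_names: list[str]
    values: np.ndarray  # (n_samples, n_features) float64
    labels: np.ndarray  # (n_samples,) object/str
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features table")
        n, f = self.values.shape
        if len(self.feature_names) != f:
            raise ValueError("feature_names length does not match the table width")
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids length does not match the table height")
        if len(set(self.feature_names)) != f:
            raise ValueError("feature names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_labels(self) -> list:
        return sorted(set(self.labels.tolist()))

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)


def _check_positions(positions: Sequence[int], n: int) -> np.ndarray:
    pos = np.asarray(positions, dtype=np.int64)
    if pos.shape[0] != n:
        raise ValueError("values and positions must have the same length")
    if np.any(pos < 0):
        raise ValueError("feature positions must be non-negative")
    if len(np.unique(pos)) != n:
        raise ValueError("feature positions must be distinct")
    return pos


def encode_sample(
    values: Sequence[float],
    positions: Sequence[int],
    levels: LevelEncoding,
    scheme: QuantizationScheme,
) -> np.ndarray:
    """Encode one sample: sum over features of rotate(level(value_f), position_f).

    Position 0 is unpermuted; feature at position p contributes its level
    vector cyclically rotated by p.
    """
    vals = np.asarray(values, dtype=np.float64)
    pos = _check_positions(positions, vals.shape[0])
    if scheme.n_levels > levels.n_levels:
        raise ValueError("quantization scheme has more levels than the encoding")
    idx = scheme.indices(vals)
    out = np.zeros(levels.d, dtype=np.int64)
    for level_index, p in zip(idx, pos):
        out += np.roll(levels.vectors[level_index], int(p) % levels.d)
    return out


def encode_matrix(
    values: np.ndarray,
    positions: Sequence[int],
    levels: LevelEncoding,
    scheme: QuantizationScheme,
) -> np.ndarray:
    """Encode a (n_samples, n_features) table into a (n_samples, d) int32 matrix."""
    vals = np.asarray(values, dtype=np.float64)
    if vals.ndim != 2:
        raise ValueError("values must be 2-D")
    pos = _check_positions(positions, vals.shape[1])
    idx = scheme.indices(vals)
    out = np.zeros((vals.shape[0], levels.d), dtype=np.int32)
    for f in range(vals.shape[1]):
        out += np.roll(levels.vectors[idx[:, f]], int(pos[f]) % levels.d, axis=1)
    return out


def feature_contributions(
    level_indices_column: np.ndarray,
    position: int,
    levels: LevelEncoding,
) -> np.ndarray:
    """Rotated level vectors one feature contributes to each sample's encoding.

    Given the pre-quantized level index of that feature in every sample,
    returns an (n_samples, d) int8 matrix; subtracting it from the full
    encodings yields the encodings of the dataset without the feature.
    """
    return np.roll(levels.vectors[np.asarray(level_indices_column)], int(position) % levels.d, axis=1)
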