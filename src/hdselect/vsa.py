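"""Bipolar hypervector algebra of the Multiply-Add-Permute (MAP) model.

Hypervectors are plain numpy integer arrays.  Atomic symbols are *bipolar*
vectors (components in {-1, +1}); bundling produces general integer vectors.
In a space of dimensionality d ~ 10 000, independently drawn bipolar vectors
are quasi-orthogonal (the cosine of a random pair has standard deviation
1/sqrt(d)), which is what makes the algebra usable as a distributed,
noise-tolerant representation:

* ``bind``    -- element-wise product; the result is dissimilar to both
  inputs but preserves their relationship (self-inverse for bipolar input).
* ``bundle``  -- element-wise sum; the result stays similar to each input,
  capturing shared structure.
* ``permute`` -- cyclic rotation; produces a dissimilar vector and is used
  to tag positional information.  It distributes exactly over both bind and
  bundle.

Scalar values are represented by *level vectors*: an ordered family of L
bipolar vectors built by progressively sign-flipping disjoint blocks of
N = floor(d / 2L) positions, so that adjacent levels are maximally similar
while distant levels approach quasi-orthogonality.  Under this disjoint-block
construction the similarity is exactly linear in the level distance:

    cosine(level_i, level_j) = 1 - 2 N |i - j| / d

All operations are integer-exact and deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "random_bipolar",
    "bind",
    "bundle",
    "negate",
    "permute",
    "cosine",
    "LevelEncoding",
    "generate_levels",
]


def _as_array(v) -> np.ndarray:
    a = np.asarray(v)
    if a.ndim != 1:
        raise ValueError(f"expected a 1-D vector, got shape {a.shape}")
    return a


def _check_same_dimension(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"dimension mismatch: {a.shape[0]} vs {b.shape[0]}")


def random_bipolar(d: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a random bipolar vector with i.i.d. components uniform on {-1, +1}."""
    if int(d) < 1:
        raise ValueError(f"dimension must be >= 1, got {d}")
    return (rng.integers(0, 2, size=int(d), dtype=np.int8) * 2 - 1).astype(np.int8)


def bind(a, b) -> np.ndarray:
    """Element-wise product (binding). Bipolar inputs give a bipolar output."""
    a, b = _as_array(a), _as_array(b)
    _check_same_dimension(a, b)
    return a.astype(np.int64) * b.astype(np.int64)


def bundle(vs: Sequence) -> np.ndarray:
    """Element-wise integer sum (bundling) of one or more equal-length vectors."""
    if len(vs) == 0:
        raise ValueError("cannot bundle an empty list of vectors")
    arrays = [_as_array(v) for v in vs]
    for v in arrays[1:]:
        _check_same_dimension(arrays[0], v)
    return np.sum(np.stack(arrays), axis=0, dtype=np.int64)


def negate(v) -> np.ndarray:
    return -_as_array(v).astype(np.int64)


def permute(v, p: int) -> np.ndarray:
    """Cyclic rotation by ``p`` positions (reduced modulo the dimension)."""
    v = _as_array(v)
    return np.roll(v, int(p) % v.shape[0])


def cosine(a, b) -> float:
    """Cosine similarity.

    A comparison involving an all-zero vector (which can arise when class
    vectors cancel during retraining) returns 0.0 with a warning instead of
    raising.
    """
    a, b = _as_array(a), _as_array(b)
    _check_same_dimension(a, b)
    af = a.astype(np.float64)
    bf = b.astype(np.float64)
    na = np.linalg.norm(af)
    nb = np.linalg.norm(bf)
    if na == 0.0 or nb == 0.0:
        warnings.warn("cosine similarity with a zero vector; returning 0.0", RuntimeWarning)
        return 0.0
    return float(af @ bf / (na * nb))


@dataclass(frozen=True)
class LevelEncoding:
    """Ordered associative memory of L quasi-orthogonal level vectors.

    Attributes
    ----------
    vectors : (L, d) int8 array, one bipolar level vector per row.
    n_flips : number of positions flipped between adjacent levels,
        N = floor(d / 2L).
    seed : the seed the family was generated from (kept so the encoding can
        be serialized as parameters and regenerated instead of stored raw).
    """

    vectors: np.ndarray
    n_flips: int
    seed: int | None = None

    @property
    def d(self) -> int:
        return int(self.vectors.shape[1])

    @property
    def n_levels(self) -> int:
        return int(self.vectors.shape[0])

    def level(self, i: int) -> np.ndarray:
        return self.vectors[i]

    def expected_similarity(self, i: int, j: int) -> float:
        """Closed-form cosine between levels i and j under disjoint-block flips."""
        return 1.0 - 2.0 * self.n_flips * abs(i - j) / self.d

    def to_json(self, path: str | Path) -> None:
        if self.seed is None:
            raise ValueError("cannot serialize a LevelEncoding without a seed")
        payload = {"d": self.d, "L": self.n_levels, "N": self.n_flips, "seed": self.seed}
        Path(path).write_text(json.dumps(payload, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LevelEncoding":
        payload = json.loads(Path(path).read_text())
        enc = generate_levels(payload["d"], payload["L"], payload["seed"])
        if enc.n_flips != payload["N"]:
            raise ValueError("inconsistent level-encoding parameters on disk")
        return enc


def generate_levels(d: int, L: int, seed: int) -> LevelEncoding:
    """Generate the ordered family of L level vectors of dimensionality d.

    Starting from a random bipolar base vector, each subsequent level flips
    the sign of N = floor(d / 2L) positions.  Flip positions are consumed in
    consecutive disjoint blocks of one global random index permutation, so
    each position flips at most once across the whole family and

        cosine(level_i, level_j) = 1 - 2 N |i - j| / d

    holds exactly for every pair.  N (L - 1) <= d / 2 guarantees feasibility.
    """
    d, L = int(d), int(L)
    if d < 1:
        raise ValueError(f"dimension must be >= 1, got {d}")
    if L < 1:
        raise ValueError(f"number of levels must be >= 1, got {L}")
    n_flips = d // (2 * L)
    if L >= 2 and n_flips == 0:
        raise ValueError(
            f"d={d} is too small for L={L} levels: floor(d/2L)=0 flips would "
            "make adjacent levels collide (need d >= 2L)"
        )
    rng = np.random.default_rng(seed)
    base = random_bipolar(d, rng)
    order = rng.permutation(d)
    vectors = np.empty((L, d), dtype=np.int8)
    vectors[0] = base
    current = base.copy()
    for i in range(1, L):
        flip = order[(i - 1) * n_flips : i * n_flips]
        current[flip] *= -1
        vectors[i] = current
    return LevelEncoding(vectors=vectors, n_flips=n_flips, seed=int(seed))
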