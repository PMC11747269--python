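"""Exhaustive 1-5-compound combination enumeration and featurization.

Each combination of selected compounds is characterized by a fixed-length
feature vector: a binary molecular-target block (bit t set iff at least
one member compound interacts with target t -- the union rule) followed by
the genomic feature vector of the assayed cancer cell line.  With the
study-scale schema of 1,093 targets and 215 genomic features the vector
has length 1,308.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations as _itercomb
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "FeatureSchema",
    "Combination",
    "CombinationFeatures",
    "CellLineProfile",
    "enumerate_combinations",
    "count_combinations",
    "featurize",
    "target_profile_index",
]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered target and genomic feature ids defining the vector layout."""

    target_ids: tuple[str, ...]
    genomic_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target ids in schema")
        if len(set(self.genomic_ids)) != len(self.genomic_ids):
            raise ValueError("duplicate genomic ids in schema")
        if not self.target_ids and not self.genomic_ids:
            raise ValueError("schema is empty")

    @property
    def total(self) -> int:
        return len(self.target_ids) + len(self.genomic_ids)

    @classmethod
    def study_scale(cls) -> "FeatureSchema":
        """The full screening schema: 1,093 targets + 215 genomic = 1,308."""
        return cls(tuple(f"T{i:04d}" for i in range(1093)),
                   tuple(f"G{i:03d}" for i in range(215)))

    @classmethod
    def desk_scale(cls, n_targets: int = 64, n_genomic: int = 16) -> "FeatureSchema":
        """A reduced schema for fast experiments and tests."""
        return cls(tuple(f"T{i:04d}" for i in range(n_targets)),
                   tuple(f"G{i:03d}" for i in range(n_genomic)))


@dataclass(frozen=True)
class Combination:
    """A non-empty set of distinct compounds, stored sorted for canonical
    identity.  The screening enumeration emits sizes 1-5; expansion scans
    may grow a combination further."""

    compounds: tuple[str, ...]
    herbs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.compounds))
        if len(set(ordered)) != len(ordered):
            raise ValueError("duplicate compounds in combination")
        if not ordered:
            raise ValueError("combination must contain at least one compound")
        object.__setattr__(self, "compounds", ordered)

    @property
    def size(self) -> int:
        return len(self.compounds)

    @property
    def id(self) -> str:
        return "+".join(self.compounds)


@dataclass(frozen=True)
class CellLineProfile:
    """Genomic feature vector of one cell line, aligned to a schema."""

    cell_line: str
    genomic: tuple[float, ...]

    @classmethod
    def from_array(cls, cell_line: str, values) -> "CellLineProfile":
        return cls(cell_line, tuple(float(v) for v in values))


@dataclass
class CombinationFeatures:
    """A combination with its target-union bits and genomic block."""

    combination: Combination
    target_bits: np.ndarray
    genomic: np.ndarray
    vector: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vector = np.concatenate([self.target_bits.astype(float),
                                      np.asarray(self.genomic, dtype=float)])


def count_combinations(n: int, min_size: int = 1, max_size: int = 5) -> int:
    """Closed-form subset count: sum of C(n, k) for k in [min_size, max_size]."""
    if n < 0 or min_size < 1 or min_size > max_size:
        raise ValueError("invalid enumeration bounds")
    return sum(math.comb(n, k) for k in range(min_size, min(max_size, n) + 1))


def enumerate_combinations(compounds: Iterable[str], min_size: int = 1,
                           max_size: int = 5) -> Iterator[Combination]:
    """Stream every size-k subset, k in [min_size, max_size], exactly once.

    Subsets are emitted in lexicographic order of the sorted compound list,
    smaller sizes first.  ``max_size`` larger than the pool is clamped with
    a warning.
    """
    pool = sorted(compounds)
    if len(set(pool)) != len(pool):
        raise ValueError("compound ids must be unique")
    if min_size < 1 or min_size > max_size:
        raise ValueError("require 1 <= min_size <= max_size")
    if max_size > len(pool):
        warnings.warn(f"max_size {max_size} exceeds pool of {len(pool)}; clamping",
                      stacklevel=2)
        max_size = len(pool)
    for k in range(min_size, max_size + 1):
        for subset in _itercomb(pool, k):
            yield Combination(subset)


def target_profile_index(edges) -> dict[str, set[str]]:
    """Index an interaction edge set as compound -> set of target ids.

    Accepts an iterable of objects with ``compound``/``target`` attributes,
    of (compound, target) pairs, or a ready-made mapping.
    """
    if isinstance(edges, Mapping):
        return {c: set(ts) for c, ts in edges.items()}
    index: dict[str, set[str]] = {}
    for e in edges:
        if hasattr(e, "compound"):
            c, t = e.compound, e.target
        else:
            c, t = e
        index.setdefault(c, set()).add(t)
    return index


def featurize(combo: Combination, edges, cell: CellLineProfile,
              schema: FeatureSchema) -> CombinationFeatures:
    """Assemble a combination's feature vector under the union rule.

    A compound with no targets contributes an all-zero block and is flagged
    with a warning rather than rejected (it can still carry provenance).
    """
    profiles = target_profile_index(edges)
    for c in combo.compounds:
        if c not in profiles:
            raise KeyError(f"compound {c!r} absent from the interaction edge set")
        if not profiles[c]:
            warnings.warn(f"compound {c!r} has zero targets", stacklevel=2)
    covered = set().union(*(profiles[c] for c in combo.compounds))
    bits = np.fromiter((1.0 if t in covered else 0.0 for t in schema.target_ids),
                       dtype=float, count=len(schema.target_ids))
    genomic = np.asarray(cell.genomic, dtype=float)
    if len(genomic) != len(schema.genomic_ids):
        raise ValueError("cell-line profile length does not match schema")
    return CombinationFeatures(combo, bits, genomic)
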