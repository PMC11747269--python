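"""De-redundancy of compounds by within-groups-linkage clustering.

Compounds with near-identical target profiles would flood the combination
enumeration with redundant samples.  They are therefore clustered on their
binary expanded-target membership vectors (Euclidean distance, which on
binary vectors is the square root of the Hamming distance) using the
SPSS-style *within-groups* agglomerative criterion: at each step, merge
the pair of clusters whose union has the smallest average over all
pairwise distances inside the merged cluster.  This differs from UPGMA,
which averages only the between-cluster distances.

The tree is cut at a distance threshold (default 5): merges are replayed
in recorded order and stop at the first merge whose criterion exceeds the
threshold, which makes the resulting partition coarsen monotonically as
the threshold grows.  One representative per cluster is then kept -- the
member with the most targets, ties broken by lexicographically smaller id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _pairs

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ClusteringConfig",
    "ClusterAssignment",
    "cluster_compounds",
    "select_representatives",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Within-groups clustering parameters (distance and linkage are fixed)."""

    cut_threshold: float = 5.0
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        if self.cut_threshold <= 0:
            raise ValueError("cut_threshold must be positive")
        if self.tie_break != "lexicographic":
            raise ValueError(f"unknown tie_break rule {self.tie_break!r}")


@dataclass
class ClusterAssignment:
    """Partition of compounds plus the full agglomeration history.

    ``merges`` lists (left member set, right member set, criterion value)
    for every merge of the complete agglomeration, in execution order; the
    partition corresponds to the cut at the configured threshold.
    """

    labels: dict[str, int]
    merges: list[tuple[frozenset, frozenset, float]]
    cut_threshold: float

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid, label in self.labels.items():
            out.setdefault(label, []).append(cid)
        for members in out.values():
            members.sort()
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def _within_group_average(sum_a: float, sum_b: float, cross: float,
                          n_a: int, n_b: int) -> float:
    n = n_a + n_b
    return (sum_a + sum_b + cross) / (n * (n - 1) / 2)


def cluster_compounds(profiles: dict[str, np.ndarray],
                      cfg: ClusteringConfig = ClusteringConfig()
                      ) -> ClusterAssignment:
    """Agglomerate compounds under the within-groups criterion and cut.

    ``profiles`` maps compound id to a numeric vector; all vectors must
    share one schema.  A single compound yields one singleton cluster.
    """
    ids = sorted(profiles)
    if not ids:
        raise ValueError("no compounds to cluster")
    lengths = {len(np.atleast_1d(profiles[i])) for i in ids}
    if len(lengths) != 1:
        raise ValueError("profile vectors must share one schema")
    n = len(ids)
    merges: list[tuple[frozenset, frozenset, float]] = []
    if n > 1:
        X = np.vstack([np.asarray(profiles[i], dtype=float) for i in ids])
        D = squareform(pdist(X, metric="euclidean"))
        # incremental bookkeeping: intra-cluster distance sums and
        # cross-cluster distance sums, updated on every merge
        clusters: dict[int, frozenset] = {k: frozenset([k]) for k in range(n)}
        intra = {k: 0.0 for k in range(n)}
        cross = {(i, j): float(D[i, j]) for i, j in _pairs(range(n), 2)}

        def cross_get(a: int, b: int) -> float:
            return cross[(a, b) if a < b else (b, a)]

        next_key = n
        while len(clusters) > 1:
            best = None
            for a, b in _pairs(sorted(clusters), 2):
                h = _within_group_average(intra[a], intra[b], cross_get(a, b),
                                          len(clusters[a]), len(clusters[b]))
                # ties (frequent on binary profiles) break on the merged
                # member ids; heights are rounded so that mathematically
                # equal criteria compare equal across computation orders
                key = (round(h, 9),
                       tuple(sorted(ids[k] for k in clusters[a] | clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b, h)
            _, a, b, h = best
            merges.append((frozenset(ids[k] for k in clusters[a]),
                           frozenset(ids[k] for k in clusters[b]), h))
            merged = clusters[a] | clusters[b]
            intra_new = intra[a] + intra[b] + cross_get(a, b)
            others = [k for k in clusters if k not in (a, b)]
            for k in others:
                cross[(min(k, next_key), max(k, next_key))] = (
                    cross_get(a, k) + cross_get(b, k))
            del clusters[a], clusters[b], intra[a], intra[b]
            clusters[next_key] = merged
            intra[next_key] = intra_new
            next_key += 1

    # cut: replay merges, stopping at the first criterion above threshold
    label_of: dict[str, int] = {cid: i for i, cid in enumerate(ids)}
    for left, right, h in merges:
        if h > cfg.cut_threshold:
            break
        keep = min(label_of[c] for c in left | right)
        for c in left | right:
            label_of[c] = keep
    # relabel to consecutive integers, ordered by smallest member id
    groups: dict[int, list[str]] = {}
    for cid, lab in label_of.items():
        groups.setdefault(lab, []).append(cid)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    labels = {cid: i for i, members in enumerate(ordered) for cid in members}
    return ClusterAssignment(labels, merges, cfg.cut_threshold)


def select_representatives(assignment: ClusterAssignment,
                           target_counts: dict[str, int]) -> list[str]:
    """One representative per cluster: most targets, then smaller id.

    The returned list is sorted by compound id.
    """
    missing = [c for c in assignment.labels if c not in target_counts]
    if missing:
        raise KeyError(f"no target count for compounds: {sorted(missing)}")
    reps = []
    for members in assignment.clusters.values():
        reps.append(min(members, key=lambda c: (-target_counts[c], c)))
    return sorted(reps)
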