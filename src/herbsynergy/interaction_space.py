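"""Compound-target interaction inference in a PCA correlation space.

Compounds and protein targets are described by (separately computed)
molecular descriptor blocks.  Each block is standardized column-wise and
reduced by principal component analysis; the study-scale defaults retain
42 compound and 237 protein components (auto-shrunk to the data rank).

Interactions are inferred from ligand-group geometry in the *compound*
component space: a target's position is the centroid of its known ligands,
and its inclusion threshold is the one-sided 95% empirical quantile
(linear interpolation) of its known ligands' distances to that centroid.
A compound is predicted to interact with a target when its Euclidean
distance to the centroid does not exceed the threshold.  Targets with
fewer than two known ligands fall back to a global pooled threshold and
are flagged.  Predicted edges are merged with known edges into an expanded
interaction network, known provenance taking precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "DescriptorMatrix",
    "InteractionEdge",
    "CorrelationSpace",
    "ligand_threshold",
    "fit_space",
    "calibrate_thresholds",
    "predict_interactions",
    "merge_networks",
]

STUDY_SCALE_DIMS = (42, 237)


def ligand_threshold(distances) -> float:
    """Inclusion threshold for a ligand group: one-sided 95% upper empirical
    quantile (linear interpolation) of member-to-centroid distances."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances")
    return float(np.quantile(d, 0.95))


@dataclass
class DescriptorMatrix:
    """Entities-by-descriptors real matrix with row ids and column names."""

    ids: list[str]
    values: np.ndarray
    columns: list[str]
    kind: str  # "compound" | "target"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("descriptor values must be 2-D")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("row count does not match ids")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column count does not match column names")
        if self.kind not in ("compound", "target"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")


@dataclass(frozen=True)
class InteractionEdge:
    """A compound-target edge with provenance and (for predictions) distance."""

    compound: str
    target: str
    provenance: str = "known"  # "known" | "predicted"
    distance: "float | None" = None

    def __post_init__(self) -> None:
        if self.provenance not in ("known", "predicted"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class _Block:
    """Standardization + PCA parameters for one descriptor block."""

    kept_columns: np.ndarray      # indices of non-constant columns
    mean: np.ndarray
    sd: np.ndarray
    components: np.ndarray        # (k, d) orthonormal rows
    variance_fraction: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept_columns] - self.mean) / self.sd

    def project(self, X: np.ndarray) -> np.ndarray:
        return self.standardize(X) @ self.components.T


@dataclass
class CorrelationSpace:
    """Fitted correlation space, optionally calibrated with thresholds."""

    compound_block: _Block
    target_block: _Block
    train_ids: list[str]
    train_projection: np.ndarray      # training compounds in component space
    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    fallback_targets: frozenset = frozenset()

    @property
    def retained_dims(self) -> tuple[int, int]:
        return (self.compound_block.n_components, self.target_block.n_components)

    @property
    def calibrated(self) -> bool:
        return bool(self.thresholds)


def _fit_block(X: np.ndarray, requested: "int | float") -> _Block:
    sd_all = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(sd_all > 0)
    if kept.size == 0:
        raise ValueError("all descriptors are constant")
    Xk = X[:, kept]
    mean, sd = Xk.mean(axis=0), Xk.std(axis=0, ddof=0)
    Z = (Xk - mean) / sd
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    ratios = pca.explained_variance_ratio_
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    if isinstance(requested, float):
        if not 0 < requested <= 1:
            raise ValueError("variance target must be in (0, 1]")
        k = int(np.searchsorted(np.cumsum(ratios), requested - 1e-12) + 1)
        k = min(k, rank)
    else:
        k = int(requested)
        if k < 1:
            raise ValueError("requested dims must be >= 1")
        if k > rank:
            warnings.warn(f"requested {k} components but rank is {rank}; reducing",
                          stacklevel=3)
            k = rank
    return _Block(kept, mean, sd, pca.components_[:k],
                  float(np.sum(ratios[:k])))


def fit_space(compounds: DescriptorMatrix, targets: DescriptorMatrix,
              variance_target: "float | None" = None,
              n_components: tuple = STUDY_SCALE_DIMS) -> CorrelationSpace:
    """Standardize both descriptor blocks and fit their PCA reductions.

    ``variance_target`` (a fraction) selects the smallest component count
    reaching that cumulative explained variance; otherwise the fixed
    ``n_components`` pair is used, shrunk to the data rank if necessary.
    """
    if compounds.kind != "compound" or targets.kind != "target":
        raise ValueError("expected a compound matrix and a target matrix")
    if len(compounds.ids) < 2 or len(targets.ids) < 2:
        raise ValueError("need at least two entities per matrix")
    req_c: "int | float" = variance_target if variance_target is not None else n_components[0]
    req_t: "int | float" = variance_target if variance_target is not None else n_components[1]
    cblock = _fit_block(compounds.values, req_c)
    tblock = _fit_block(targets.values, req_t)
    return CorrelationSpace(cblock, tblock, list(compounds.ids),
                            cblock.project(compounds.values))


def calibrate_thresholds(space: CorrelationSpace, known_edges) -> CorrelationSpace:
    """Derive per-target centroids and 95%-quantile distance thresholds.

    Uses the training compounds stored in the space.  Targets with a
    single known ligand get the global pooled threshold and are flagged in
    ``fallback_targets``.
    """
    pos = {cid: space.train_projection[i] for i, cid in enumerate(space.train_ids)}
    ligands: dict[str, list[str]] = {}
    for e in known_edges:
        c, t = (e.compound, e.target) if hasattr(e, "compound") else e
        if c in pos:
            ligands.setdefault(t, []).append(c)
    if not ligands:
        raise ValueError("no known edges reference training compounds")

    centroids, thresholds = {}, {}
    pooled: list[np.ndarray] = []
    singletons = []
    for t, members in ligands.items():
        P = np.vstack([pos[c] for c in members])
        centroid = P.mean(axis=0)
        centroids[t] = centroid
        d = np.linalg.norm(P - centroid, axis=1)
        if len(members) >= 2:
            thresholds[t] = ligand_threshold(d)
            pooled.append(d)
        else:
            singletons.append(t)
    if singletons:
        if not pooled:
            raise ValueError("every target has a single ligand; cannot pool")
        global_threshold = ligand_threshold(np.concatenate(pooled))
        for t in singletons:
            thresholds[t] = global_threshold
    # strictly positive thresholds even for degenerate point groups
    thresholds = {t: max(v, 1e-12) for t, v in thresholds.items()}
    return replace(space, centroids=centroids, thresholds=thresholds,
                   fallback_targets=frozenset(singletons))


def predict_interactions(space: CorrelationSpace,
                         compounds: DescriptorMatrix) -> set:
    """Emit a predicted edge for every compound within a target's threshold.

    Compounds whose descriptor rows are not finite cannot be projected and
    are skipped with a warning.
    """
    if not space.calibrated:
        raise ValueError("space is not calibrated; run calibrate_thresholds first")
    finite = np.all(np.isfinite(compounds.values), axis=1)
    if not np.all(finite):
        bad = [compounds.ids[i] for i in np.flatnonzero(~finite)]
        warnings.warn(f"excluding unprojectable compounds: {bad}", stacklevel=2)
    X = space.compound_block.project(compounds.values[finite])
    ids = [cid for cid, ok in zip(compounds.ids, finite) if ok]
    edges = set()
    for t, centroid in space.centroids.items():
        d = np.linalg.norm(X - centroid, axis=1)
        thr = space.thresholds[t]
        for i in np.flatnonzero(d <= thr):
            edges.add(InteractionEdge(ids[i], t, "predicted", float(d[i])))
    return edges


def merge_networks(known, predicted) -> tuple[set, dict]:
    """Union known and predicted edges; duplicates collapse to known.

    Returns the merged edge set and a summary with the numbers of distinct
    compounds, targets and edges.
    """
    merged: dict[tuple[str, str], InteractionEdge] = {}
    for e in predicted:
        merged[(e.compound, e.target)] = e
    for e in known:
        prev = merged.get((e.compound, e.target))
        dist = prev.distance if prev is not None else e.distance
        merged[(e.compound, e.target)] = InteractionEdge(
            e.compound, e.target, "known", dist)
    edges = set(merged.values())
    summary = {
        "n_compounds": len({e.compound for e in edges}),
        "n_targets": len({e.target for e in edges}),
        "n_edges": len(edges),
    }
    return edges, summary
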