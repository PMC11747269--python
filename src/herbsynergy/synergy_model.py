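"""Feed-forward synergy ranker mapping combination features to pseudo-IC50.

The network takes a combination feature vector (binary target-union block
plus cell-line genomic block), passes it through two ReLU hidden layers
(200 and 100 units by default, each followed by dropout) and emits two
heads: a linear regression head predicting the standardized pseudo-IC50
(lower = stronger predicted synergy; typical values are negative for the
best combinations) and a sigmoid classification head for positive vs
negative synergy.  Training minimizes MSE + w * binary cross-entropy with
Adam; class labels default to thresholding the pseudo-IC50 at the corpus
median.  All weight initialization and batch shuffling is driven by the
config seed, so training is deterministic.

Study-scale hyperparameters (lr 1e-5, batch 128, 200 epochs, input 1,308)
are the defaults; desk-scale experiments typically use lr 1e-3 and a
reduced schema via the config, never by editing code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .combinations import (CellLineProfile, Combination, CombinationFeatures,
                           FeatureSchema, featurize)

__all__ = [
    "SynergyModelConfig",
    "SynergyPrediction",
    "SynergyModel",
    "train",
    "rank_combinations",
    "rank_predictions",
    "expansion_scan",
]


@dataclass(frozen=True)
class SynergyModelConfig:
    input_dim: int = 1308
    hidden: tuple[int, int] = (200, 100)
    dropout: float = 0.0
    learning_rate: float = 1e-5
    batch_size: int = 128
    epochs: int = 200
    head_weight: float = 0.5     # weight of the classification loss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("layer sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be positive")


@dataclass
class SynergyPrediction:
    """Model output for one combination."""

    combination_id: str
    pseudo_ic50: float
    synergy_class: str            # "positive" | "negative"
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class SynergyModel:
    """Two-hidden-layer dual-head regressor/classifier on numpy."""

    def __init__(self, cfg: SynergyModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d, (h1, h2) = cfg.input_dim, cfg.hidden
        def he(fan_in, shape):
            return rng.normal(scale=np.sqrt(2.0 / fan_in), size=shape)
        self.W1, self.b1 = he(d, (d, h1)), np.zeros(h1)
        self.W2, self.b2 = he(h1, (h1, h2)), np.zeros(h2)
        self.wr, self.br = he(h2, (h2, 1)), np.zeros(1)
        self.wc, self.bc = he(h2, (h2, 1)), np.zeros(1)
        self._rng = rng

    @property
    def _params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2,
                self.wr, self.br, self.wc, self.bc]

    def _forward(self, X: np.ndarray, train: bool = False):
        a1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        m1 = m2 = None
        p_keep = 1.0 - self.cfg.dropout
        if train and self.cfg.dropout > 0:
            m1 = (self._rng.random(a1.shape) < p_keep) / p_keep
            a1 = a1 * m1
        a2 = np.maximum(a1 @ self.W2 + self.b2, 0.0)
        if train and self.cfg.dropout > 0:
            m2 = (self._rng.random(a2.shape) < p_keep) / p_keep
            a2 = a2 * m2
        yr = (a2 @ self.wr + self.br).ravel()
        logit = (a2 @ self.wc + self.bc).ravel()
        prob = 1.0 / (1.0 + np.exp(-logit))
        return yr, prob, (a1, a2, m1, m2)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pseudo-IC50 and positive-synergy probability for feature rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.cfg.input_dim:
            raise ValueError(
                f"feature dim {X.shape[1]} != model input {self.cfg.input_dim}")
        yr, prob, _ = self._forward(X, train=False)
        return yr, prob

    def _backward(self, X, y, c, yr, prob, cache):
        n = len(y)
        a1, a2, m1, m2 = cache
        w = self.cfg.head_weight
        d_yr = 2.0 * (yr - y) / n                 # MSE
        d_logit = w * (prob - c) / n              # BCE through sigmoid
        g_wr = a2.T @ d_yr[:, None]
        g_br = np.array([d_yr.sum()])
        g_wc = a2.T @ d_logit[:, None]
        g_bc = np.array([d_logit.sum()])
        d_a2 = d_yr[:, None] @ self.wr.T + d_logit[:, None] @ self.wc.T
        if m2 is not None:
            d_a2 = d_a2 * m2
        d_z2 = d_a2 * (a2 > 0)
        g_W2 = a1.T @ d_z2
        g_b2 = d_z2.sum(axis=0)
        d_a1 = d_z2 @ self.W2.T
        if m1 is not None:
            d_a1 = d_a1 * m1
        d_z1 = d_a1 * (a1 > 0)
        g_W1 = X.T @ d_z1
        g_b1 = d_z1.sum(axis=0)
        return [g_W1, g_b1, g_W2, g_b2, g_wr, g_br, g_wc, g_bc]


def train(X, y, cfg: SynergyModelConfig, validation_fraction: float = 0.1,
          class_labels=None) -> tuple[SynergyModel, dict]:
    """Train a synergy model; returns the model and per-epoch loss history.

    ``class_labels`` defaults to ``y <= median(y)`` (1 = positive synergy,
    i.e. a pseudo-IC50 in the stronger half of the corpus).  The history
    dict has ``train_loss`` and, when a validation split is held out,
    ``val_loss`` per epoch.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if X.shape[0] == 0:
        raise ValueError("empty corpus")
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"corpus feature dim {X.shape[1]} != "
                         f"config input_dim {cfg.input_dim}")
    c = (np.asarray(class_labels, dtype=float).ravel()
         if class_labels is not None else (y <= np.median(y)).astype(float))

    rng = np.random.default_rng(cfg.seed + 1)
    n = X.shape[0]
    n_val = int(round(validation_fraction * n))
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xt, yt, ct = X[tr_idx], y[tr_idx], c[tr_idx]

    model = SynergyModel(cfg)
    opt = _Adam(model._params, cfg.learning_rate)
    history: dict = {"train_loss": [], "val_loss": []}
    w = cfg.head_weight
    eps = 1e-12

    def loss_on(Xs, ys, cs) -> float:
        yr, prob, _ = model._forward(Xs)
        mse = float(np.mean((yr - ys) ** 2))
        bce = float(-np.mean(cs * np.log(prob + eps)
                             + (1 - cs) * np.log(1 - prob + eps)))
        return mse + w * bce

    for _ in range(cfg.epochs):
        perm = rng.permutation(len(Xt))
        for start in range(0, len(Xt), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            Xb, yb, cb = Xt[idx], yt[idx], ct[idx]
            yr, prob, cache = model._forward(Xb, train=True)
            grads = model._backward(Xb, yb, cb, yr, prob, cache)
            opt.step(model._params, grads)
        history["train_loss"].append(loss_on(Xt, yt, ct))
        if n_val:
            history["val_loss"].append(loss_on(X[val_idx], y[val_idx], c[val_idx]))
    if not n_val:
        del history["val_loss"]
    return model, history


def rank_predictions(preds: Iterable[SynergyPrediction]) -> list[SynergyPrediction]:
    """Ascending pseudo-IC50 order (strongest synergy first), stable ties by id."""
    return sorted(preds, key=lambda p: (p.pseudo_ic50, p.combination_id))


def rank_combinations(model: SynergyModel,
                      features: Iterable[CombinationFeatures],
                      batch_size: int = 1024) -> list[SynergyPrediction]:
    """Score a stream of featurized combinations and rank them."""
    preds: list[SynergyPrediction] = []
    batch: list[CombinationFeatures] = []

    def flush():
        if not batch:
            return
        M = np.vstack([f.vector for f in batch])
        yr, prob = model.predict(M)
        for f, r, p in zip(batch, yr, prob):
            preds.append(SynergyPrediction(
                f.combination.id, float(r),
                "positive" if p >= 0.5 else "negative", float(p)))
        batch.clear()

    for f in features:
        batch.append(f)
        if len(batch) >= batch_size:
            flush()
    flush()
    return rank_predictions(preds)


def expansion_scan(model: SynergyModel, base: Combination,
                   candidates: "list[str]", edges, cell: CellLineProfile,
                   schema: FeatureSchema) -> list[tuple[Combination, float]]:
    """Score the base combination and each cumulative extension of it.

    Candidates are added one at a time in the given order (base+1, base+2,
    ...), each extended set featurized under the union rule; rows are
    returned in extension order, base first.  Extensions may exceed the
    1-5 enumeration window (up to the 9-compound representation limit).
    """
    if set(candidates) & set(base.compounds):
        raise ValueError("candidates must be disjoint from the base combination")
    rows = []
    members = list(base.compounds)
    for extra in [None, *candidates]:
        if extra is not None:
            members.append(extra)
        combo = Combination(tuple(members))
        feats = featurize(combo, edges, cell, schema)
        yr, _ = model.predict(feats.vector[None, :])
        rows.append((combo, float(yr[0])))
    return rows
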