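"""Synthetic worlds with known ground truth for every pipeline stage.

Three generators cover the data the screen needs:

* a descriptor world -- compound and target descriptor matrices with a
  planted ligand-ball geometry (every true ligand of a target lies within
  ``ligand_ball_radius`` of that target's ligand centroid, background
  compounds lie well outside), giving a binary interaction truth for the
  correlation-space predictor;
* Hill-curve dose-response data for single agents and fixed-ratio
  mixtures, with a configurable Loewe-interaction parameter ``lambda``
  (0 = exact additivity, > 0 synergy, < 0 antagonism; the Loewe-additive
  mixture IC50 is scaled by exp(-lambda));
* a synergy training corpus -- combination feature vectors labelled by a
  latent additive-plus-pairwise-interaction function of target bits with
  genomic modifiers, standardized to the pseudo-IC50 scale (lower = more
  synergistic) and recomputable through an exposed oracle.

All outputs are reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .combinations import FeatureSchema
from .interaction_space import DescriptorMatrix

__all__ = [
    "SynthConfig",
    "SimulatedCurve",
    "LatentSynergyFunction",
    "SynergyCorpus",
    "gen_descriptor_world",
    "hill_response",
    "loewe_mixture_ic50",
    "gen_dose_response",
    "gen_synergy_corpus",
]


@dataclass(frozen=True)
class SynthConfig:
    """Shared knobs for all synthetic generators.

    ``extra_ligand_fraction`` is the probability that a compound beyond
    the one guaranteed ligand per target is itself a ligand of a random
    target (the rest are background, placed outside every ligand ball).
    """

    seed: int = 0
    n_compounds: int = 60
    n_targets: int = 8
    n_descriptors_compound: int = 24
    n_descriptors_target: int = 40
    ligand_ball_radius: float = 1.0
    extra_ligand_fraction: float = 0.6
    hill_slope: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    interaction_lambda: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_targets", "n_descriptors_compound",
                     "n_descriptors_target"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.ligand_ball_radius < 0:
            raise ValueError("ligand_ball_radius must be non-negative")
        if not self.top > self.bottom:
            raise ValueError("top must exceed bottom")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.extra_ligand_fraction <= 1:
            raise ValueError("extra_ligand_fraction must be in [0, 1]")


def _ball_point(rng: np.random.Generator, centroid: np.ndarray,
                radius: float) -> np.ndarray:
    d = centroid.size
    v = rng.normal(size=d)
    v /= np.linalg.norm(v)
    return centroid + radius * rng.random() ** (1.0 / d) * v


def gen_descriptor_world(cfg: SynthConfig
                         ) -> tuple[DescriptorMatrix, DescriptorMatrix, frozenset]:
    """Generate descriptor matrices plus the true interaction edge set.

    Target ligand centroids are spread at ~10x the ball radius, so ligand
    groups are well separated from the diffuse background; background
    compounds are rejection-sampled to lie > 2x the radius from every
    centroid (acceptance failure after 1000 tries raises, which cannot
    happen at the default geometry).
    """
    if cfg.n_compounds < cfg.n_targets:
        raise ValueError("need at least one compound per target")
    rng = np.random.default_rng(cfg.seed)
    d = cfg.n_descriptors_compound
    scale = max(10.0 * cfg.ligand_ball_radius, 1.0)
    centroids = rng.normal(scale=scale, size=(cfg.n_targets, d))
    cids = [f"C{i:04d}" for i in range(cfg.n_compounds)]
    tids = [f"T{i:03d}" for i in range(cfg.n_targets)]

    X = np.empty((cfg.n_compounds, d))
    edges = set()
    for i in range(cfg.n_compounds):
        if i < cfg.n_targets:
            t = i  # guarantee one ligand per target
        elif rng.random() < cfg.extra_ligand_fraction:
            t = int(rng.integers(cfg.n_targets))
        else:
            t = -1
        if t >= 0:
            X[i] = _ball_point(rng, centroids[t], cfg.ligand_ball_radius)
            edges.add((cids[i], tids[t]))
        else:
            for _ in range(1000):
                x = rng.normal(scale=scale, size=d)
                dist = np.linalg.norm(centroids - x, axis=1).min()
                if dist > 2.0 * cfg.ligand_ball_radius:
                    X[i] = x
                    break
            else:
                raise RuntimeError("could not place a background compound")

    compounds = DescriptorMatrix(cids, X, [f"cd{j}" for j in range(d)], "compound")
    targets = DescriptorMatrix(
        tids, rng.normal(size=(cfg.n_targets, cfg.n_descriptors_target)),
        [f"td{j}" for j in range(cfg.n_descriptors_target)], "target")
    return compounds, targets, frozenset(edges)


def hill_response(conc, ic50: float, cfg: SynthConfig) -> np.ndarray:
    """Noise-free decreasing Hill viability; midpoint at conc = ic50."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    conc = np.asarray(conc, dtype=float)
    return cfg.bottom + (cfg.top - cfg.bottom) / (
        1.0 + (conc / ic50) ** cfg.hill_slope)


def loewe_mixture_ic50(fractions: dict[str, float],
                       single_ic50s: dict[str, float]) -> float:
    """Loewe-additive mixture IC50: solves sum_i f_i * C / IC50_i = 1."""
    denom = 0.0
    for name, f in fractions.items():
        ic50 = single_ic50s[name]
        if ic50 <= 0:
            raise ValueError(f"non-positive IC50 for {name!r}")
        denom += f / ic50
    return 1.0 / denom


@dataclass
class SimulatedCurve:
    """A simulated assay curve with its generating truth."""

    concentrations: np.ndarray
    viabilities: np.ndarray
    true_ic50: float


def gen_dose_response(cfg: SynthConfig, mixture, single_ic50s: dict[str, float],
                      doses=None, rng: "np.random.Generator | None" = None
                      ) -> SimulatedCurve:
    """Simulate a CCK-8 curve for a fixed-ratio mixture (or single agent).

    The mixture's generating IC50 is the Loewe-additive value scaled by
    exp(-lambda), so lambda > 0 produces CI < 1 downstream.  The default
    dose grid is 8 log-spaced points spanning 0.01-100x the smallest
    single-agent IC50.  Gaussian viability noise of sd ``noise_sd`` (in
    percent viability) is added when non-zero.
    """
    fractions = mixture.fractions if hasattr(mixture, "fractions") else dict(mixture)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    ic50_mix = loewe_mixture_ic50(fractions, single_ic50s) * np.exp(
        -cfg.interaction_lambda)
    if doses is None:
        smallest = min(single_ic50s[n] for n in fractions)
        doses = np.geomspace(0.01 * smallest, 100.0 * smallest, 8)
    doses = np.asarray(doses, dtype=float)
    viab = hill_response(doses, ic50_mix, cfg)
    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(scale=cfg.noise_sd, size=doses.shape)
        noise = np.clip(noise, -3.0 * cfg.noise_sd, 3.0 * cfg.noise_sd)
        viab = viab + noise
    return SimulatedCurve(doses, viab, float(ic50_mix))


@dataclass
class LatentSynergyFunction:
    """The ground-truth labelling function of a synergy corpus.

    raw(x) = t . w_target + sum_p w_pair[p] * t[i_p] * t[j_p] + g . w_genomic
    where t is the target-bit block and g the genomic block of the feature
    vector; labels are (raw - mean) / sd on the corpus standardization.
    """

    n_targets: int
    w_target: np.ndarray
    pair_index: np.ndarray      # (m, 2) target index pairs
    w_pair: np.ndarray
    w_genomic: np.ndarray
    mean: float = 0.0
    sd: float = 1.0

    def raw(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        t = X[:, :self.n_targets]
        g = X[:, self.n_targets:]
        y = t @ self.w_target + g @ self.w_genomic
        if len(self.w_pair):
            y = y + (t[:, self.pair_index[:, 0]]
                     * t[:, self.pair_index[:, 1]]) @ self.w_pair
        return y

    def oracle(self, X: np.ndarray) -> np.ndarray:
        """Noise-free standardized labels for feature rows."""
        return (self.raw(X) - self.mean) / self.sd


@dataclass
class SynergyCorpus:
    """Feature matrix, pseudo-IC50 labels and the latent truth behind them.

    ``compound_targets`` maps each synthetic compound to its target indices
    so that new combinations over the same pool can be featurized and
    scored against the oracle; ``cells`` holds the genomic profiles.
    """

    X: np.ndarray
    y: np.ndarray
    combos: list[tuple[str, ...]]
    latent: LatentSynergyFunction
    compound_targets: dict[str, np.ndarray]
    cells: np.ndarray
    schema: FeatureSchema = field(repr=False, default=None)


def gen_synergy_corpus(cfg: SynthConfig, schema: FeatureSchema,
                       n_samples: int = 5000, n_cell_lines: int = 5,
                       max_size: int = 5) -> SynergyCorpus:
    """Sample a labelled combination corpus over a synthetic compound pool.

    Each of ``cfg.n_compounds`` synthetic compounds hits 1 + Poisson(2)
    random schema targets; a sample is a random 1..max_size compound
    subset paired with one of ``n_cell_lines`` standard-normal genomic
    profiles.  Labels come from the latent function plus N(0, noise_sd)
    noise, standardized over the corpus.
    """
    n_t, n_g = len(schema.target_ids), len(schema.genomic_ids)
    if n_t == 0:
        raise ValueError("schema has no targets")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(cfg.seed)

    profiles = []
    for _ in range(cfg.n_compounds):
        k = 1 + rng.poisson(2)
        profiles.append(np.unique(rng.integers(n_t, size=k)))
    cells = rng.normal(size=(n_cell_lines, n_g))

    m = max(2 * n_t, 1)
    pair_index = rng.integers(n_t, size=(m, 2))
    pair_index = pair_index[pair_index[:, 0] != pair_index[:, 1]]
    latent = LatentSynergyFunction(
        n_targets=n_t,
        w_target=rng.normal(scale=0.5, size=n_t),
        pair_index=pair_index,
        w_pair=rng.normal(scale=1.0, size=len(pair_index)),
        w_genomic=rng.normal(scale=0.3, size=n_g),
    )

    X = np.zeros((n_samples, n_t + n_g))
    combos = []
    names = [f"S{i:04d}" for i in range(cfg.n_compounds)]
    for i in range(n_samples):
        size = int(rng.integers(1, max_size + 1))
        members = rng.choice(cfg.n_compounds, size=size, replace=False)
        bits = np.zeros(n_t)
        for c in members:
            bits[profiles[c]] = 1.0
        X[i, :n_t] = bits
        X[i, n_t:] = cells[rng.integers(n_cell_lines)]
        combos.append(tuple(sorted(names[c] for c in members)))

    raw = latent.raw(X)
    if cfg.noise_sd > 0:
        raw = raw + rng.normal(scale=cfg.noise_sd, size=n_samples)
    sd = float(raw.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate corpus: zero label variance")
    latent.mean, latent.sd = float(raw.mean()), sd
    y = (raw - latent.mean) / latent.sd
    return SynergyCorpus(X, y, combos, latent,
                         dict(zip(names, profiles)), cells, schema)
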