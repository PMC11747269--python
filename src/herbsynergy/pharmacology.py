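"""Dose-response analytics for CCK-8 viability assays.

Implements the three quantitative primitives of the wet-lab arm of the
screen:

* viability from raw absorbances,
* IC50 estimation by four-parameter logistic (4PL) regression with a
  log-linear interpolation fallback, and
* the Chou-Talalay combination index (CI) generalized to k components,

    CI = sum_i D_i / IC50_i,   D_i = IC50_mix * f_i,

  where f_i are molar (or volume) fractions of the mixture and IC50_i the
  single-agent potencies.  CI < 1 indicates synergy, CI = 1 additivity
  (Loewe null model), CI > 1 antagonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ADDITIVE_BAND",
    "MixtureDesign",
    "DoseResponseCurve",
    "CombinationAssay",
    "viability",
    "four_parameter_logistic",
    "fit_ic50",
    "compute_ci",
]

#: half-width of the CI band reported as "additive" in text summaries;
#: the raw CI value is always preserved alongside the verdict.
ADDITIVE_BAND = 0.05


def viability(absorbance_test: float, absorbance_control: float,
              absorbance_blank: float) -> float:
    """Percent cell viability from CCK-8 absorbances.

    ``100 * (test - blank) / (control - blank)``.  Values above 100% or
    below 0% are reported as-is (they occur with noisy plates).

    Raises
    ------
    ValueError
        If the control absorbance does not exceed the blank.
    """
    denom = absorbance_control - absorbance_blank
    if denom <= 0:
        raise ValueError(
            "control absorbance must exceed blank absorbance "
            f"(control={absorbance_control}, blank={absorbance_blank})"
        )
    return 100.0 * (absorbance_test - absorbance_blank) / denom


@dataclass(frozen=True)
class MixtureDesign:
    """Fixed-ratio mixture: (component id, fraction) pairs summing to 1.

    Fractions are molar fractions for compound mixtures and volume
    fractions of equal-strength stocks for extract blends.
    """

    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = 0.0
        for name, f in self.components:
            if f <= 0:
                raise ValueError(f"fraction for {name!r} must be positive, got {f}")
            total += f
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total!r})")

    @classmethod
    def from_ratio(cls, ids: "list[str] | tuple[str, ...]",
                   parts: "list[float] | tuple[float, ...]") -> "MixtureDesign":
        """Build a design from an integer (or real) ratio such as 64:305:4:5."""
        if len(ids) != len(parts):
            raise ValueError("ids and parts must have equal length")
        total = float(sum(parts))
        if total <= 0:
            raise ValueError("ratio parts must sum to a positive value")
        return cls(tuple((i, p / total) for i, p in zip(ids, parts)))

    @property
    def fractions(self) -> dict[str, float]:
        return dict(self.components)


def four_parameter_logistic(conc, top, bottom, hill, ic50):
    """Decreasing 4PL viability curve; equals (top+bottom)/2 at conc = ic50."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


@dataclass
class DoseResponseCurve:
    """A dose-response dataset with its fitted 4PL parameters."""

    concentrations: np.ndarray
    viabilities: np.ndarray
    top: float = float("nan")
    bottom: float = float("nan")
    hill: float = float("nan")
    ic50: float = float("nan")
    rss: float = float("nan")
    converged: bool = False
    extrapolated: bool = False

    def predicted(self, conc) -> np.ndarray:
        return four_parameter_logistic(conc, self.top, self.bottom,
                                       self.hill, self.ic50)


def _absolute_ic50(top: float, bottom: float, hill: float, rel_ic50: float) -> float:
    """Concentration where the fitted curve crosses 50% absolute viability."""
    if not (bottom < 50.0 < top):
        return float("nan")
    return rel_ic50 * ((top - 50.0) / (50.0 - bottom)) ** (1.0 / hill)


def _loglinear_ic50(conc: np.ndarray, viab: np.ndarray) -> float:
    """Fallback: interpolate the 50% crossing linearly in log10 concentration."""
    order = np.argsort(conc)
    c, v = conc[order], viab[order]
    for i in range(len(c) - 1):
        lo, hi = v[i], v[i + 1]
        if (lo - 50.0) * (hi - 50.0) <= 0 and lo != hi:
            t = (lo - 50.0) / (lo - hi)
            return 10 ** (np.log10(c[i]) + t * (np.log10(c[i + 1]) - np.log10(c[i])))
    return float("nan")


def fit_ic50(concentrations, viabilities) -> DoseResponseCurve:
    """Fit a four-parameter logistic and report the absolute-50% IC50.

    The bottom asymptote is constrained to be non-negative.  If the
    optimizer fails, or the fitted asymptotes do not bracket 50%, the IC50
    falls back to log-linear interpolation between the bracketing points
    and ``converged`` is left False (or ``extrapolated`` set, respectively).
    """
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if conc.ndim != 1 or conc.shape != viab.shape:
        raise ValueError("concentrations and viabilities must be equal-length 1-D")
    if len(conc) < 4:
        raise ValueError("need at least 4 concentrations for a 4PL fit")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    curve = DoseResponseCurve(conc, viab)
    p0 = (max(float(viab.max()), 60.0), max(float(viab.min()), 0.0), 1.0,
          float(np.exp(np.mean(np.log(conc)))))
    bounds = ([40.0, 0.0, 0.05, conc.min() / 1e4],
              [300.0, 60.0, 20.0, conc.max() * 1e4])
    try:
        popt, _ = curve_fit(four_parameter_logistic, conc, viab, p0=p0,
                            bounds=bounds, maxfev=20000)
        top, bottom, hill, rel = (float(x) for x in popt)
        curve.top, curve.bottom, curve.hill = top, bottom, hill
        curve.rss = float(np.sum((four_parameter_logistic(conc, *popt) - viab) ** 2))
        ic50 = _absolute_ic50(top, bottom, hill, rel)
        if math.isnan(ic50):
            curve.extrapolated = True
            ic50 = _loglinear_ic50(conc, viab)
        else:
            curve.converged = True
        curve.ic50 = ic50
    except RuntimeError:
        curve.ic50 = _loglinear_ic50(conc, viab)
    if math.isnan(curve.ic50):
        curve.extrapolated = True
    return curve


@dataclass
class CombinationAssay:
    """A fixed-ratio combination assay and its combination index."""

    mixture: MixtureDesign
    ic50_mix: float
    single_ic50: dict[str, float]
    ci: float = field(init=False)
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        if self.ic50_mix <= 0:
            raise ValueError("mixture IC50 must be positive")
        ci = 0.0
        for name, f in self.mixture.components:
            try:
                single = self.single_ic50[name]
            except KeyError:
                raise ValueError(f"missing single-agent IC50 for {name!r}") from None
            if single <= 0:
                raise ValueError(f"single-agent IC50 for {name!r} must be positive")
            ci += self.ic50_mix * f / single
        self.ci = ci
        if abs(ci - 1.0) < ADDITIVE_BAND:
            self.verdict = "additive"
        elif ci < 1.0:
            self.verdict = "synergy"
        else:
            self.verdict = "antagonism"


def compute_ci(mixture: MixtureDesign, ic50_mix: float,
               single_ic50: dict[str, float]) -> CombinationAssay:
    """Generalized Chou-Talalay combination index for a k-component mixture."""
    return CombinationAssay(mixture, ic50_mix, single_ic50)
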