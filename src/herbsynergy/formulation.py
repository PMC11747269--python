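"""Content-to-molar formulation of compound combinations from herbal extracts.

HPLC reports the content of each marker compound as mg per g crude drug.
At an extract dose of ``dose`` mg crude drug per mL, the molar
concentration of a compound of molecular weight ``mw`` g/mol is

    uM = content [mg/g] * dose [mg/mL] / mw [g/mol] * 1000.

A combination's formulation at that dose is the vector of component
concentrations; for display the components are rounded half-away-from-zero
to integers (the "ratio string", e.g. 64:305:4:5) and the total is the sum
of the rounded components.  Molar fractions for mixture designs are taken
from the unrounded concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .pharmacology import MixtureDesign

__all__ = [
    "ExtractContent",
    "FormulationResult",
    "to_micromolar",
    "round_half_away",
    "build_mixture",
    "blend_extracts",
    "compare_origins",
]


@dataclass(frozen=True)
class ExtractContent:
    """Marker-compound contents of one herbal extract lot.

    ``contents`` maps compound id to mg per g crude drug; a compound absent
    from the mapping was not detected in this extract (e.g. scopoletin in
    the water extract of Prunella vulgaris).
    """

    herb: str
    solvent: str
    contents: dict[str, float]
    lot: str = ""

    def __post_init__(self) -> None:
        for name, c in self.contents.items():
            if c < 0:
                raise ValueError(f"negative content for {name!r}: {c}")


def to_micromolar(content_mg_per_g: float, dose_mg_per_ml: float,
                  mw_g_per_mol: float) -> float:
    """Convert an mg/g content to µM at the given crude-drug dose."""
    if content_mg_per_g < 0:
        raise ValueError("content must be non-negative")
    if dose_mg_per_ml <= 0:
        raise ValueError("dose must be positive")
    if mw_g_per_mol <= 0:
        raise ValueError("molecular weight must be positive")
    return content_mg_per_g * dose_mg_per_ml / mw_g_per_mol * 1000.0


def round_half_away(x: float) -> int:
    """Round half away from zero (5.5 -> 6, -5.5 -> -6)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class FormulationResult:
    """A combination formulated at an extract dose."""

    members: tuple[str, ...]
    dose: float
    micromolar: dict[str, float]          # unrounded µM per member
    feasible: bool
    missing: tuple[str, ...] = ()
    ratio: tuple[int, ...] = field(init=False)
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = tuple(round_half_away(self.micromolar.get(m, 0.0))
                           for m in self.members)
        self.total = sum(self.ratio)

    @property
    def ratio_string(self) -> str:
        return ":".join(str(r) for r in self.ratio)


def build_mixture(extract: ExtractContent, members: "list[str] | tuple[str, ...]",
                  dose: float, mw_table: dict[str, float],
                  ) -> tuple[FormulationResult, "MixtureDesign | None"]:
    """Formulate a combination at the extract's natural proportions.

    Returns the formulation plus a :class:`MixtureDesign` whose molar
    fractions come from the unrounded µM values.  If any member was not
    detected in the extract the formulation is infeasible for this solvent
    and the design is ``None``.
    """
    members = tuple(members)
    missing = tuple(m for m in members if m not in extract.contents)
    for m in members:
        if m not in mw_table:
            raise KeyError(f"no molecular weight for compound {m!r}")
    micromolar = {m: to_micromolar(extract.contents[m], dose, mw_table[m])
                  for m in members if m not in missing}
    if missing:
        return FormulationResult(members, dose, micromolar, False, missing), None
    result = FormulationResult(members, dose, micromolar, True)
    total_um = sum(micromolar.values())
    design = MixtureDesign(tuple((m, micromolar[m] / total_um) for m in members))
    return result, design


def blend_extracts(a: ExtractContent, b: ExtractContent,
                   parts_a: float, parts_b: float) -> ExtractContent:
    """Volume blend of two equal-strength (crude mg/mL) extract stocks.

    Per gram of blended crude drug, each content is the parts-weighted mean
    of the lot contents; compounds detected in either lot are retained.
    """
    if parts_a <= 0 or parts_b <= 0:
        raise ValueError("blend parts must be positive")
    total = parts_a + parts_b
    names = set(a.contents) | set(b.contents)
    contents = {n: (parts_a * a.contents.get(n, 0.0)
                    + parts_b * b.contents.get(n, 0.0)) / total
                for n in names}
    return ExtractContent(
        herb=f"{a.herb}:{b.herb} ({parts_a:g}:{parts_b:g})",
        solvent=a.solvent, contents=contents,
        lot=f"{a.lot}+{b.lot}")


def compare_origins(lots: "list[ExtractContent]", members, dose: float,
                    mw_table: dict[str, float]) -> list[tuple[str, FormulationResult]]:
    """Formulate one combination across geographic lots, ranked by total µM.

    Returns (lot id, formulation) pairs in descending order of total
    concentration; ties keep the input lot order (stable sort).
    """
    if len(lots) < 2:
        raise ValueError("need at least two lots to compare")
    rows = [(lot.lot or lot.herb, build_mixture(lot, members, dose, mw_table)[0])
            for lot in lots]
    rows.sort(key=lambda r: -r[1].total)
    return rows
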