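"""Published reference measurements for the PVL-TH herb-pair study system.

These are the printed wet-lab and prediction inputs for the Prunella
vulgaris L. (PVL) - Taraxacum mongolicum Hand.-Mazz. (TH) screen on MCF-7
cells: extract and single-compound IC50s, fixed-ratio combination assays
with their reported combination indices, HPLC marker contents per solvent,
per-origin lot formulations, and the published model-score orderings for
the named superior combinations (F973, T271, T1685, V3859).

They serve as worked-example inputs and golden values; everything derived
from them (CI values, ratio strings, totals, orderings) is recomputed by
the package at run time.

Compound abbreviations: CA caffeic acid, ROA rosmarinic acid, PCA
p-coumaric acid, ET esculetin, CHA chlorogenic acid, CIA cichoric acid,
ST scopoletin, RT rutin, LT luteolin, QT quercetin, HYP hyperoside.
"""

from __future__ import annotations

from .formulation import ExtractContent

__all__ = [
    "MOLECULAR_WEIGHTS",
    "SINGLE_COMPOUND_IC50_UM",
    "EXTRACT_SINGLE_IC50",
    "EXTRACT_BLEND_ASSAYS",
    "EQUIMOLAR_COMBINATIONS",
    "ACTUAL_RATIO_COMBINATIONS",
    "EXTENDED_COMBINATIONS",
    "EXTRACT_CONTENTS",
    "ORIGIN_LOT_TABLES",
    "PREDICTED_SCORES",
    "EXPANSION_SCORES",
    "DEFAULT_DOSE_MG_PER_ML",
]

#: g/mol, used to link mg/g contents to µM ratios.
MOLECULAR_WEIGHTS: dict[str, float] = {
    "CA": 180.16, "ROA": 360.31, "PCA": 164.16, "ET": 178.14,
    "CHA": 354.31, "CIA": 474.37, "ST": 192.17, "RT": 610.52,
    "LT": 286.24, "QT": 302.24, "HP": 504.44,
}

#: extract dose (mg crude drug per mL) at which all ratio strings are stated.
DEFAULT_DOSE_MG_PER_ML = 25.0

#: single-compound IC50s on MCF-7 (µM).
SINGLE_COMPOUND_IC50_UM: dict[str, float] = {
    "ST": 6607.75, "CA": 885.67, "ET": 305.13, "ROA": 75.82, "LT": 59.63,
    "PCA": 1132.03, "RT": 826.61, "CHA": 295.18, "CIA": 68.86,
}

#: single-extract IC50s (mg/mL crude drug) per solvent.
EXTRACT_SINGLE_IC50: dict[str, dict[str, float]] = {
    "water": {"PVL": 10.70, "TH": 43.20},
    "ethanol": {"PVL": 6.47, "TH": 11.68},
}

#: (solvent, PVL parts, TH parts, blend IC50 mg/mL, reported CI).
EXTRACT_BLEND_ASSAYS: list[tuple[str, int, int, float, float]] = [
    ("water", 1, 1, 15.91, 0.93),
    ("water", 1, 2, 15.06, 0.70),
    ("water", 2, 1, 9.57, 0.67),
    ("ethanol", 1, 1, 9.61, 1.15),
    ("ethanol", 1, 2, 5.96, 0.65),
    ("ethanol", 2, 1, 5.54, 0.73),
]

#: equimolar superior-combination assays:
#: (combo id, members, predicted score, IC50 µM, reported CI).
EQUIMOLAR_COMBINATIONS: list[tuple[str, tuple[str, ...], float, float, float]] = [
    ("T1685", ("CHA", "ROA", "ST"), -1.1150, 57.22, 0.32),
    ("T271", ("CHA", "CIA", "CA"), -1.0999, 61.31, 0.39),
    ("V3859", ("CA", "RT", "LT", "PCA", "ROA"), -1.0961, 76.46, 0.51),
    ("F973", ("CA", "ROA", "PCA", "ET"), -1.0739, 96.42, 0.45),
]

#: actual-ratio assays at 25 mg/mL extract dose:
#: (solvent, extract label, combo id, members, ratio, total µM, IC50 µM, CI).
ACTUAL_RATIO_COMBINATIONS: list[tuple[str, str, str, tuple[str, ...],
                                      tuple[int, ...], int, float, float]] = [
    ("water", "PVL", "F973", ("CA", "ROA", "PCA", "ET"),
     (180, 109, 10, 6), 305, 71.86, 0.39),
    ("water", "TH", "T271", ("CHA", "CIA", "CA"),
     (37, 131, 19), 187, 83.16, 0.91),
    ("water", "PVL:TH (2:1)", "V3859", ("CA", "RT", "LT", "PCA", "ROA"),
     (126, 2, 1, 8, 72), 209, 31.77, 0.17),
    ("ethanol", "PVL", "F973", ("CA", "ROA", "PCA", "ET"),
     (64, 305, 4, 5), 378, 59.20, 0.64),
    ("ethanol", "TH", "T271", ("CHA", "CIA", "CA"),
     (30, 106, 50), 186, 21.94, 0.20),
    ("ethanol", "PVL:TH (2:1)", "V3859", ("CA", "RT", "LT", "PCA", "ROA"),
     (59, 12, 9, 4, 203), 287, 23.38, 0.24),
    ("ethanol", "PVL:TH (2:1)", "T1685", ("CHA", "ROA", "ST"),
     (10, 203, 6), 219, 21.50, 0.27),
]

#: extended combinations at extract ratios:
#: (extract label, combo id, members, ratio, IC50 µM, reported CI).
EXTENDED_COMBINATIONS: list[tuple[str, str, tuple[str, ...],
                                  tuple[int, ...], float, float]] = [
    ("PVL ethanol", "F973-1", ("CA", "ROA", "PCA", "ET", "RT"),
     (64, 305, 4, 5, 14), 101.84, 1.07),
    ("PVL ethanol", "F973-2", ("CA", "ROA", "PCA", "ET", "RT", "ST"),
     (64, 305, 4, 5, 14, 9), 125.11, 1.29),
    ("TH ethanol", "T271-1", ("CHA", "CIA", "CA", "LT"),
     (30, 106, 50, 27), 123.40, 1.25),
    ("TH ethanol", "T271-2", ("CHA", "CIA", "CA", "LT", "PCA"),
     (30, 106, 50, 27, 5), 113.40, 1.12),
    ("PVL:TH 2:1 water", "V3859-3",
     ("CA", "RT", "LT", "PCA", "ROA", "CIA", "CHA", "ET"),
     (126, 2, 1, 8, 72, 44, 12, 4), 121.03, 0.81),
    ("PVL:TH 2:1 ethanol", "T1685-6",
     ("CHA", "ROA", "ST", "CA", "CIA", "PCA", "LT", "ET", "RT"),
     (10, 203, 6, 59, 35, 4, 9, 3, 12), 85.03, 0.86),
]

#: HPLC marker contents (mg per g crude drug) by (herb, solvent).
#: Compounds absent from a mapping were not detected in that extract.
EXTRACT_CONTENTS: dict[tuple[str, str], ExtractContent] = {
    ("PVL", "water"): ExtractContent("PVL", "water", {
        "CA": 1.293, "PCA": 0.066, "ROA": 1.564, "ET": 0.039,
        "RT": 0.04, "QT": 0.043,
    }),
    ("PVL", "ethanol"): ExtractContent("PVL", "ethanol", {
        "CA": 0.459, "PCA": 0.023, "ST": 0.066, "ROA": 4.397,
        "ET": 0.036, "RT": 0.329, "HYP": 0.182, "QT": 0.027,
    }),
    ("TH", "water"): ExtractContent("TH", "water", {
        "CHA": 0.517, "CIA": 2.491, "CA": 0.137, "LT": 0.036,
        "PCA": 0.057, "RT": 0.093,
    }),
    ("TH", "ethanol"): ExtractContent("TH", "ethanol", {
        "CHA": 0.422, "CIA": 2.017, "CA": 0.359, "LT": 0.303,
        "PCA": 0.035, "RT": 0.215,
    }),
}

#: per-origin formulations of the superior combinations in 50%-ethanol
#: extracts at 25 mg/mL: combo id -> list of (lot id, origin, ratio, total µM).
ORIGIN_LOT_TABLES: dict[str, list[tuple[str, str, tuple[int, ...], int]]] = {
    "F973": [
        ("PVL-1", "Henan", (42, 235, 3, 5), 285),
        ("PVL-2", "Hubei", (45, 269, 3, 4), 320),
        ("PVL-3", "Jiangsu", (33, 110, 3, 4), 150),
        ("PVL-4", "Sichuan", (38, 305, 2, 6), 351),
        ("PVL-5", "Anhui", (50, 364, 2, 5), 420),
    ],
    "T271": [
        ("TH-1", "Henan", (33, 120, 32), 186),
        ("TH-2", "Anhui", (19, 90, 28), 136),
        ("TH-3", "Shanxi", (30, 127, 74), 230),
        ("TH-4", "Gansu", (22, 96, 67), 185),
        ("TH-5", "Hunan", (45, 156, 62), 263),
    ],
}

#: published model scores (standardized pseudo-IC50 scale, lower = more
#: synergistic) for top-ranked combinations; used as supplied-value ordering
#: fixtures, never as recomputable quantities.
PREDICTED_SCORES: dict[str, float] = {
    "T1685": -1.1150, "T271": -1.0999, "V3859": -1.0961, "F973": -1.0739,
}

#: published scores for the sequential-expansion experiment.
EXPANSION_SCORES: dict[str, float] = {
    "T1685-2": -0.9324, "F973-1": -0.4618, "T1685-3": -0.3310,
    "T1685-1": -0.1312, "F973-2": -0.0530, "V3859-1": 0.0112,
    "V3859-3": 1.8148, "F973-3": 1.8148, "F973-4": 1.8148,
    "T271-1": 1.8293, "T271-2": 1.8865, "V3859-2": 1.9002,
    "T271-3": 2.3813,
}
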