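"""Plate combinatorics and full-factorial media optimization.

Covers the experiment-design side of the screen: the 96-condition
enrichment-plate layout (media x pH x antibiotic grid), the
enrichment -> subculture expansion arithmetic, and the 3x3x3 Terrific
Broth (TB) media-optimization design with its fold-change and
main-effect analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, InvariantError, ParameterError
from .screening import PLATE_COLUMNS, PLATE_ROWS, parse_well

__all__ = [
    "WellCondition",
    "PlateLayout",
    "FactorialDesign",
    "ResponseTable",
    "ScreenCounts",
    "MainEffect",
    "enrichment_layout",
    "expand_screen",
    "full_factorial",
    "default_tb_factors",
    "fold_changes",
    "main_effects",
]

VALID_PH = (5.8, 6.5, 7.2, 8.0)
ANTIBIOTICS = ("none", "penicillinG", "kanamycin")


@dataclass(frozen=True)
class WellCondition:
    """Medium, optional buffered pH, and antibiotic for one well."""

    medium: str
    pH: Optional[float] = None
    antibiotic: str = "none"

    def __post_init__(self) -> None:
        if self.pH is not None and self.pH not in VALID_PH:
            raise InvariantError(f"pH must be one of {VALID_PH}, got {self.pH}")
        if self.antibiotic not in ANTIBIOTICS:
            raise InvariantError(f"antibiotic must be one of {ANTIBIOTICS}")


@dataclass(frozen=True)
class PlateLayout:
    """A 96-well plate: incubation conditions plus well -> condition map."""

    plate_id: str
    temperature: float  # degrees C
    shaken: bool
    wells: tuple[tuple[str, WellCondition], ...]

    def __post_init__(self) -> None:
        coords = [w for w, _ in self.wells]
        if len(coords) != 96 or len(set(coords)) != 96:
            raise InvariantError("a plate layout requires 96 unique wells")
        for w in coords:
            parse_well(w)

    def condition(self, well: str) -> WellCondition:
        for w, c in self.wells:
            if w == well:
                return c
        raise KeyError(well)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"plate": self.plate_id, "well": w, "medium": c.medium,
                 "pH": c.pH, "antibiotic": c.antibiotic}
                for w, c in self.wells
            ]
        )


# The enrichment-plate media grid: rows A-H by base columns 1-4, repeated
# across the three antibiotic blocks (columns 1-4 none, 5-8 penicillin G,
# 9-12 kanamycin).  Entries are (medium, pH-or-None).
_BASE_GRID: dict[str, tuple[tuple[str, Optional[float]], ...]] = {
    "A": (("NB", None), ("NB", 5.8), ("1/10 NB", 5.8), ("MB", 5.8)),
    "B": (("LB", None), ("NB", 6.5), ("1/10 NB", 6.5), ("MB", 6.5)),
    "C": (("MB", None), ("NB", 7.2), ("1/10 NB", 7.2), ("MB", 7.2)),
    "D": (("TB", None), ("NB", 8.0), ("1/10 NB", 8.0), ("MB", 8.0)),
    "E": (("dH2O", None), ("ISP1", None), ("NB + 0.5% butanol", None), ("1/10 MB", 5.8)),
    "F": (("M9 glycerol", None), ("NB/SW", None), ("ASW", None), ("1/10 MB", 6.5)),
    "G": (("M9 glucose", None), ("Emerson", None), ("ASW glycerol", None), ("1/10 MB", 7.2)),
    "H": (("M9 arabinose", None), ("R2", None), ("ASW glucose", None), ("1/10 MB", 8.0)),
}


def enrichment_layout(
    plate_id: str = "enrichment-1", temperature: float = 30.0, shaken: bool = True
) -> PlateLayout:
    """The standard 96-condition enrichment-plate layout.

    Rows A-H x columns 1-12; the 8x4 media/pH grid repeats across three
    four-column antibiotic blocks (no antibiotic, penicillin G, kanamycin).
    Well D5 is therefore TB + penicillin G, B1 is LB with no antibiotic,
    A9 is NB + kanamycin.
    """
    wells = []
    for row in PLATE_ROWS:
        for col in PLATE_COLUMNS:
            medium, ph = _BASE_GRID[row][(col - 1) % 4]
            antibiotic = ANTIBIOTICS[(col - 1) // 4]
            wells.append((f"{row}{col}", WellCondition(medium, ph, antibiotic)))
    return PlateLayout(plate_id=plate_id, temperature=temperature, shaken=shaken,
                       wells=tuple(wells))


class ScreenCounts(NamedTuple):
    enrichment_cultures: int
    subculture_plates: int
    total_conditions: int


def expand_screen(
    n_enrichment: int, wells_per_plate: int = 96, subcultures_per_enrichment: int = 4
) -> ScreenCounts:
    """Enrichment -> subculture combinatorics.

    Four 96-well enrichment plates each subcultured into four plates give
    384 enrichment cultures, 16 subculture plates, and 1536 screened
    culture conditions.
    """
    if n_enrichment < 1 or wells_per_plate < 1 or subcultures_per_enrichment < 1:
        raise ParameterError("all counts must be >= 1")
    return ScreenCounts(
        enrichment_cultures=n_enrichment * wells_per_plate,
        subculture_plates=n_enrichment * subcultures_per_enrichment,
        total_conditions=n_enrichment * subcultures_per_enrichment * wells_per_plate,
    )


# ---------------------------------------------------------------------------
# Full-factorial media optimization


def default_tb_factors() -> list[tuple[str, tuple[float, ...]]]:
    """TB optimization factors: g/L levels (low, mid, high) per component."""
    return [
        ("tryptone", (3.0, 12.0, 18.0)),
        ("yeast_extract", (6.0, 24.0, 36.0)),
        ("glycerol", (1.0, 4.0, 8.0)),
    ]


@dataclass(frozen=True)
class FactorialDesign:
    """All level combinations of the factors, in a deterministic order.

    ``formulations`` maps formulation ids (``TB01``..``TBk``) to their
    (factor -> level value) assignments; ``reference_id`` labels the
    combination of mid levels (standard TB, ``TB14`` in the 3x3x3 design).
    """

    factors: tuple[tuple[str, tuple[float, ...]], ...]
    formulations: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]
    reference_id: str

    def __post_init__(self) -> None:
        expected = int(np.prod([len(levels) for _, levels in self.factors]))
        if len(self.formulations) != expected:
            raise InvariantError(
                f"formulation count {len(self.formulations)} != product of "
                f"level counts {expected}"
            )
        if self.reference_id not in {fid for fid, _ in self.formulations}:
            raise InvariantError(f"reference {self.reference_id!r} not in design")

    def levels(self, formulation_id: str) -> dict[str, float]:
        for fid, combo in self.formulations:
            if fid == formulation_id:
                return dict(combo)
        raise KeyError(formulation_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fid, combo in self.formulations:
            row = {"formulation_id": fid}
            row.update({f"{name}_g_per_L": value for name, value in combo})
            rows.append(row)
        return pd.DataFrame(rows)


def full_factorial(
    factors: Optional[Sequence[tuple[str, Sequence[float]]]] = None,
    id_prefix: str = "TB",
) -> FactorialDesign:
    """Cartesian product of factor levels, last factor varying fastest.

    Ids are assigned positionally (``TB01``, ``TB02``, ...).  The
    reference combination takes each factor's middle level; with factors
    ordered tryptone, yeast extract, glycerol at levels low < mid < high
    the all-mid standard TB formulation lands at position 14 (``TB14``).
    """
    if factors is None:
        factors = default_tb_factors()
    factors = tuple((name, tuple(float(v) for v in levels)) for name, levels in factors)
    if not factors or any(len(levels) < 1 for _, levels in factors):
        raise ParameterError("every factor needs at least one level")
    names = [name for name, _ in factors]
    width = max(2, len(str(int(np.prod([len(l) for _, l in factors])))))
    formulations = []
    reference_combo = tuple(
        (name, levels[(len(levels) - 1) // 2]) for name, levels in factors
    )
    reference_id = None
    for i, combo in enumerate(itertools.product(*(levels for _, levels in factors))):
        fid = f"{id_prefix}{i + 1:0{width}d}"
        assignment = tuple(zip(names, combo))
        if assignment == reference_combo:
            reference_id = fid
        formulations.append((fid, assignment))
    assert reference_id is not None
    return FactorialDesign(
        factors=factors, formulations=tuple(formulations), reference_id=reference_id
    )


@dataclass(frozen=True)
class ResponseTable:
    """Titer measurements: (formulation_id, strain_id, replicate, titer)."""

    records: tuple[tuple[str, str, int, float], ...]
    reference_id: str

    def __post_init__(self) -> None:
        if any(t < 0 for *_, t in self.records):
            raise InvariantError("titers must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.records),
            columns=["formulation_id", "strain_id", "replicate", "titer"],
        )


def fold_changes(table: ResponseTable) -> dict[str, float]:
    """Mean titer of each formulation divided by the reference's mean titer.

    The reference formulation maps to exactly 1.0 by construction.
    Raises :class:`InputError` when the reference has no records or a
    zero mean titer (the fold is then undefined).
    """
    df = table.to_frame()
    means = df.groupby("formulation_id")["titer"].mean()
    if table.reference_id not in means.index:
        raise InputError(f"no titer records for reference {table.reference_id!r}")
    ref = means[table.reference_id]
    if ref == 0:
        raise InputError("reference formulation has zero mean titer; fold undefined")
    folds = (means / ref).to_dict()
    folds[table.reference_id] = 1.0
    return folds


@dataclass(frozen=True)
class MainEffect:
    """Per-level mean titers for one factor, plus a monotonicity label."""

    factor: str
    level_means: tuple[tuple[float, float], ...]  # (level value, mean titer)
    trend: str  # increasing | decreasing | non-monotone

    def means(self) -> list[float]:
        return [m for _, m in self.level_means]


def _trend(means: Sequence[float]) -> str:
    if all(b > a for a, b in zip(means, means[1:])):
        return "increasing"
    if all(b < a for a, b in zip(means, means[1:])):
        return "decreasing"
    return "non-monotone"


def main_effects(table: ResponseTable, design: FactorialDesign) -> list[MainEffect]:
    """Marginal mean titer at each level of each factor.

    The level mean averages every record of every formulation carrying
    that level; the trend label requires a strict ordering across the
    factor's levels (ties give ``non-monotone``).  Raises
    :class:`InputError` if any design formulation lacks records.
    """
    df = table.to_frame()
    have = set(df["formulation_id"])
    missing = [fid for fid, _ in design.formulations if fid not in have]
    if missing:
        raise InputError(f"no titer records for formulation(s): {', '.join(missing)}")
    level_lookup = {fid: dict(combo) for fid, combo in design.formulations}
    effects = []
    for name, levels in design.factors:
        df_factor = df.assign(level=[level_lookup[f][name] for f in df["formulation_id"]])
        means = df_factor.groupby("level")["titer"].mean()
        level_means = tuple((lv, float(means[lv])) for lv in levels)
        effects.append(MainEffect(name, level_means, _trend([m for _, m in level_means])))
    return effects
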