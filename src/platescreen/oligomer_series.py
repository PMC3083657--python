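"""Repeat-unit (oligomer) mass arithmetic and series detection.

A homologous oligomer family — e.g. linear 3-hydroxybutyric acid
oligoesters, whose members differ by the 86-amu C4H6O2 residue — shows up
in screening data as an arithmetic progression of ion masses.  This
module computes oligomer masses from residue formulas and recovers such
progressions from observed mass lists.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Mapping, Optional, Sequence, Union

from pyteomics import mass as _ptmass

from .errors import InvariantError, ParameterError

__all__ = [
    "ElementalFormula",
    "OligomerSeries",
    "residue_mass",
    "oligomer_mass",
    "detect_series",
    "consolidate_masses",
    "HYDROXYBUTYRATE",
    "WATER",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map, e.g. ``ElementalFormula.parse("C4H6O2")``."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for elem, n in self.counts:
            if elem in seen:
                raise InvariantError(f"duplicate element {elem!r} in formula")
            seen.add(elem)
            if not isinstance(n, int) or n < 0:
                raise InvariantError(f"count for {elem!r} must be a non-negative integer")

    @classmethod
    def parse(cls, formula: str) -> "ElementalFormula":
        """Parse a Hill-style formula string like ``'C4H6O2'`` or ``'H2O'``."""
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise InvariantError(f"unparseable formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula) or not counts:
            raise InvariantError(f"unparseable formula {formula!r}")
        return cls(tuple(sorted(counts.items())))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(sorted(mapping.items())))

    def to_string(self) -> str:
        return "".join(f"{e}{n if n != 1 else ''}" for e, n in self.counts if n > 0)

    def __bool__(self) -> bool:
        return any(n > 0 for _, n in self.counts)


HYDROXYBUTYRATE = ElementalFormula.parse("C4H6O2")  # 3-hydroxybutyric acid residue
WATER = ElementalFormula.parse("H2O")

FormulaLike = Union[ElementalFormula, str, Mapping[str, int]]


def _as_formula(f: FormulaLike) -> ElementalFormula:
    if isinstance(f, ElementalFormula):
        return f
    if isinstance(f, str):
        return ElementalFormula.parse(f)
    return ElementalFormula.from_mapping(f)


def residue_mass(formula: FormulaLike, mode: str = "monoisotopic") -> float:
    """Mass of a formula from standard atomic masses (monoisotopic or average)."""
    if mode not in ("monoisotopic", "average"):
        raise ParameterError(f"mode must be 'monoisotopic' or 'average', got {mode!r}")
    formula = _as_formula(formula)
    if not formula:
        return 0.0
    comp = _ptmass.Composition(formula=formula.to_string())
    return float(_ptmass.calculate_mass(composition=comp, average=(mode == "average")))


def oligomer_mass(
    n: int,
    residue: FormulaLike = HYDROXYBUTYRATE,
    end_group: FormulaLike = WATER,
    mode: str = "monoisotopic",
) -> float:
    """Neutral mass of a linear oligomer: n residues plus one end group.

    The default residue/end-group pair is the linear oligoester
    convention for hydroxy acids: n condensed C4H6O2 residues capped by
    one water.  oligomer_mass(7) = 620.268, oligomer_mass(8) = 706.305.
    """
    if n < 0:
        raise ParameterError(f"n must be >= 0, got {n}")
    return n * residue_mass(residue, mode) + residue_mass(end_group, mode)


@dataclass(frozen=True)
class OligomerSeries:
    """An arithmetic progression of observed masses.

    ``repeat_mass`` is the mean of consecutive differences and
    ``residual`` the worst deviation of any single difference from it.
    """

    member_masses: tuple[float, ...]
    repeat_mass: float
    residual: float

    def __post_init__(self) -> None:
        ms = self.member_masses
        if len(ms) < 2:
            raise InvariantError("a series needs at least 2 members")
        if any(b <= a for a, b in zip(ms, ms[1:])):
            raise InvariantError("member masses must be strictly increasing")

    @property
    def n_members(self) -> int:
        return len(self.member_masses)


def _series_from_masses(masses: Sequence[float]) -> OligomerSeries:
    diffs = [b - a for a, b in zip(masses, masses[1:])]
    repeat = fmean(diffs)
    residual = max(abs(d - repeat) for d in diffs)
    return OligomerSeries(tuple(masses), repeat, residual)


def is_valid_progression(
    masses: Sequence[float],
    tol: float,
    candidate_repeats: Optional[Sequence[float]] = None,
) -> bool:
    """True if the sorted masses form a progression: every consecutive
    difference within ``tol`` of their mean (and of a candidate repeat,
    when candidates are given)."""
    if len(masses) < 2:
        return False
    s = _series_from_masses(sorted(masses))
    if s.residual > tol:
        return False
    if candidate_repeats is not None:
        return any(abs(s.repeat_mass - c) <= tol for c in candidate_repeats)
    return True


def consolidate_masses(masses: Iterable[float], tol: float) -> list[float]:
    """Collapse repeated observations of the same ion to one mass.

    Single-linkage clustering on the sorted masses (split where the gap
    exceeds ``tol``), each cluster reported as its mean.  Useful before
    :func:`detect_series` when the same compound was observed in several
    wells with small mass jitter.
    """
    if not tol > 0:
        raise ParameterError(f"tol must be > 0, got {tol}")
    values = sorted(masses)
    if not values:
        return []
    groups: list[list[float]] = [[values[0]]]
    for m in values[1:]:
        if m - groups[-1][-1] <= tol:
            groups[-1].append(m)
        else:
            groups.append([m])
    return [fmean(g) for g in groups]


def detect_series(
    masses: Iterable[float],
    tol: float = 0.3,
    min_len: int = 2,
    candidate_repeats: Optional[Sequence[float]] = None,
) -> list[OligomerSeries]:
    """Find maximal repeat-unit series among observed masses.

    A series is a subset whose sorted consecutive differences all agree
    with their own mean within ``tol`` (restricted near
    ``candidate_repeats`` when given).  Only maximal subsets are kept —
    no valid strict superset exists within the input — and, to avoid
    combinatorial duplicates of one family, any series sharing >= 2
    members with a longer reported series is suppressed.  Results are
    sorted by member count, descending.
    """
    if not tol > 0:
        raise ParameterError(f"tol must be > 0, got {tol}")
    if min_len < 2:
        raise ParameterError(f"min_len must be >= 2, got {min_len}")
    values = sorted(set(float(m) for m in masses))
    n = len(values)
    if n < 2:
        return []

    valid: list[frozenset[int]] = []

    # DFS over increasing index chains.  Prune on difference spread: a chain
    # whose consecutive-difference spread exceeds 2*tol can never satisfy the
    # residual bound (the best possible residual is spread/2), and the spread
    # only grows under extension.
    def extend(chain: list[int], diffs: list[float]) -> None:
        last = chain[-1]
        for j in range(last + 1, n):
            d = values[j] - values[last]
            nd = diffs + [d]
            if max(nd) - min(nd) > 2 * tol:
                continue
            chain.append(j)
            if len(chain) >= min_len and is_valid_progression(
                [values[i] for i in chain], tol, candidate_repeats
            ):
                valid.append(frozenset(chain))
            extend(chain, nd)
            chain.pop()

    for start in range(n - 1):
        extend([start], [])

    # maximality: drop any valid set strictly contained in another valid set
    valid_sets = set(valid)
    maximal = [s for s in valid_sets if not any(s < t for t in valid_sets)]

    series = [_series_from_masses(sorted(values[i] for i in s)) for s in maximal]
    series.sort(key=lambda s: (-s.n_members, s.member_masses))

    # overlap suppression: one chemical family should be reported once
    reported: list[OligomerSeries] = []
    for s in series:
        members = set(s.member_masses)
        if any(
            r.n_members > s.n_members and len(members & set(r.member_masses)) >= 2
            for r in reported
        ):
            continue
        reported.append(s)
    return reported
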