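"""Screen plate-well extracts against a target library.

Matching is two-dimensional (retention time and observed mass, each with
its own tolerance), quantification is the matched feature's peak area,
and identity is confirmed by MS/MS spectral similarity when both the
library entry and the extract feature carry a fragmentation spectrum.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InputError, InvariantError, ParameterError
from .ms_data import ChromatographicFeature, MassSpectrum
from .target_library import DEFAULT_MZ_TOL, DEFAULT_RT_TOL, TargetLibrary

__all__ = [
    "WellExtract",
    "HitRecord",
    "PlateScreenReport",
    "ms2_similarity",
    "screen_well",
    "screen_plate_set",
    "DEFAULT_MS2_BIN_WIDTH",
    "DEFAULT_MS2_THRESHOLD",
]

DEFAULT_MS2_BIN_WIDTH = 0.5  # amu
DEFAULT_MS2_THRESHOLD = 0.7

_WELL_RE = re.compile(r"^([A-H])(\d{1,2})$")

PLATE_ROWS = "ABCDEFGH"
PLATE_COLUMNS = tuple(range(1, 13))


def parse_well(well: str) -> tuple[str, int]:
    """Validate and split a 96-well coordinate like ``'D5'`` into (row, column)."""
    m = _WELL_RE.match(well)
    if not m or not (1 <= int(m.group(2)) <= 12):
        raise InvariantError(
            f"well {well!r} is not a 96-well coordinate (rows A-H, columns 1-12)"
        )
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class WellExtract:
    """The features found in one well's culture-broth extract."""

    plate_id: str
    well: str
    features: tuple[ChromatographicFeature, ...] = ()

    def __post_init__(self) -> None:
        parse_well(self.well)
        object.__setattr__(self, "features", tuple(self.features))


@dataclass(frozen=True)
class HitRecord:
    """One library entry matched in one well."""

    plate_id: str
    well: str
    entry_id: int
    delta_rt: float  # feature RT minus entry RT, minutes
    delta_mz: float  # feature mass minus entry mass, amu
    quantity: float  # matched feature's peak area, counts*min
    ms2_score: Optional[float] = None
    confirmed: bool = False
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise InvariantError("hit quantity must be >= 0")
        if self.confirmed and self.ms2_score is None:
            raise InvariantError("a confirmed hit must carry an ms2_score")


@dataclass(frozen=True)
class PlateScreenReport:
    """Aggregated screen over a set of plates.

    ``hits`` holds every match; the summary properties are recomputed on
    access so they can never disagree with the hit lists.
    """

    hits: tuple[HitRecord, ...]
    n_wells_screened: int

    @property
    def wells_with_hits(self) -> list[tuple[str, str]]:
        """Sorted (plate, well) pairs containing at least one confirmed hit."""
        return sorted({(h.plate_id, h.well) for h in self.hits if h.confirmed})

    @property
    def wells_with_any_match(self) -> list[tuple[str, str]]:
        """Sorted (plate, well) pairs with at least one tolerance match."""
        return sorted({(h.plate_id, h.well) for h in self.hits})

    @property
    def per_entry_counts(self) -> dict[int, int]:
        """entry_id -> number of wells where that entry was matched."""
        counts: dict[int, int] = {}
        for h in self.hits:
            counts[h.entry_id] = counts.get(h.entry_id, 0) + 1
        return dict(sorted(counts.items()))


def _binned_sqrt_vector(spec: MassSpectrum, bin_width: float) -> dict[int, float]:
    binned: dict[int, float] = {}
    for mz, inten in spec.peaks:
        b = int(math.floor(mz / bin_width))
        binned[b] = binned.get(b, 0.0) + inten
    return {b: math.sqrt(v) for b, v in binned.items()}


def ms2_similarity(a: MassSpectrum, b: MassSpectrum, bin_width: float = DEFAULT_MS2_BIN_WIDTH) -> float:
    """Cosine similarity of square-root-transformed, binned MS/MS spectra.

    Peak intensities are summed onto a fixed m/z grid of width
    ``bin_width``, square-root transformed (damping dominance of the base
    peak), and compared by normalized dot product.  The score is in [0, 1],
    symmetric, and invariant to uniform intensity scaling.  An empty
    spectrum scores 0 with a warning.
    """
    if not bin_width > 0:
        raise ParameterError(f"bin_width must be > 0, got {bin_width}")
    va = _binned_sqrt_vector(a, bin_width)
    vb = _binned_sqrt_vector(b, bin_width)
    na = math.sqrt(sum(v * v for v in va.values()))
    nb = math.sqrt(sum(v * v for v in vb.values()))
    if na == 0.0 or nb == 0.0:
        warnings.warn("MS2 similarity against an empty spectrum is defined as 0")
        return 0.0
    dot = sum(v * vb[k] for k, v in va.items() if k in vb)
    return min(1.0, dot / (na * nb))


def screen_well(
    extract: WellExtract,
    library: TargetLibrary,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    ms2_threshold: float = DEFAULT_MS2_THRESHOLD,
    bin_width: float = DEFAULT_MS2_BIN_WIDTH,
) -> list[HitRecord]:
    """Match every library entry against one well's features.

    For each entry, the candidate features within both tolerances are
    ranked by smallest |mass error| then |RT error| and the best one
    becomes the hit.  When both sides carry MS2 spectra the similarity is
    computed and ``confirmed`` set by ``ms2_threshold``; otherwise the hit
    is reported unconfirmed with no score.
    """
    if not rt_tol > 0 or not mz_tol > 0:
        raise ParameterError("rt_tol and mz_tol must be > 0")
    hits: list[HitRecord] = []
    feats = extract.features
    if not feats:
        return hits
    f_mz = np.array([f.mz for f in feats])
    f_rt = np.array([f.rt_apex for f in feats])
    for entry in library.entries:
        dmz = f_mz - entry.mz
        drt = f_rt - entry.rt
        mask = (np.abs(dmz) <= mz_tol) & (np.abs(drt) <= rt_tol)
        if not mask.any():
            continue
        idx = np.nonzero(mask)[0]
        best = min(idx, key=lambda i: (abs(dmz[i]), abs(drt[i]), i))
        feat = feats[best]
        score: Optional[float] = None
        confirmed = False
        if entry.ms2 is not None and feat.ms2 is not None:
            score = ms2_similarity(entry.ms2, feat.ms2, bin_width)
            confirmed = score >= ms2_threshold
        hits.append(
            HitRecord(
                plate_id=extract.plate_id,
                well=extract.well,
                entry_id=entry.entry_id,
                delta_rt=float(drt[best]),
                delta_mz=float(dmz[best]),
                quantity=feat.area,
                ms2_score=score,
                confirmed=confirmed,
                name=entry.name,
            )
        )
    return hits


def screen_plate_set(
    extracts: Sequence[WellExtract],
    library: TargetLibrary,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    ms2_threshold: float = DEFAULT_MS2_THRESHOLD,
    bin_width: float = DEFAULT_MS2_BIN_WIDTH,
) -> PlateScreenReport:
    """Screen a whole set of plates and aggregate into a report.

    Raises :class:`InputError` on duplicate (plate, well) coordinates.
    The report is independent of the order in which wells are supplied.
    """
    seen: set[tuple[str, str]] = set()
    for ex in extracts:
        key = (ex.plate_id, ex.well)
        if key in seen:
            raise InputError(f"duplicate extract for plate {key[0]!r} well {key[1]!r}")
        seen.add(key)
    ordered = sorted(extracts, key=lambda e: (e.plate_id, parse_well(e.well)))
    hits: list[HitRecord] = []
    for ex in ordered:
        hits.extend(
            screen_well(ex, library, rt_tol=rt_tol, mz_tol=mz_tol,
                        ms2_threshold=ms2_threshold, bin_width=bin_width)
        )
    return PlateScreenReport(hits=tuple(hits), n_wells_screened=len(ordered))
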