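"""Target-molecule ("standards") libraries.

A library entry is a metabolite characterized by retention time, the mass
of its most abundant ion, and optionally its MS/MS spectrum.  Libraries
are built by merging characterized features across chromatographic
fractions, deduplicating anything that co-locates within both an RT and a
mass tolerance, and are serialized either as NIST-style MSP text or as a
lossless native JSON dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .errors import FormatError, InvariantError, ParameterError
from .ms_data import ChromatographicFeature, MassSpectrum

__all__ = [
    "LibraryEntry",
    "TargetLibrary",
    "build_library",
    "query",
    "read_msp",
    "write_msp",
    "read_json",
    "write_json",
    "ec_reference_library",
    "EC_CHARACTERIZATIONS",
]

DEFAULT_RT_TOL = 0.1  # minutes, suited to a 6-min UPLC gradient
DEFAULT_MZ_TOL = 0.3  # amu, unit-resolution ion trap


@dataclass(frozen=True)
class LibraryEntry:
    """One target molecule: RT (minutes), observed mass (amu), optional MS2."""

    entry_id: int
    rt: float
    mz: float
    name: Optional[str] = None
    ms2: Optional[MassSpectrum] = None
    source: str = ""
    area: float = 0.0  # area of the representative feature, used for dedup

    def __post_init__(self) -> None:
        if not self.rt > 0:
            raise InvariantError(f"entry rt must be > 0, got {self.rt}")
        if not self.mz > 0:
            raise InvariantError(f"entry mz must be > 0, got {self.mz}")


@dataclass(frozen=True)
class TargetLibrary:
    """An ordered catalog of :class:`LibraryEntry` with unique ids.

    ``rt_tol``/``mz_tol`` record the tolerances used at build time; the
    dedup guarantee is that no two entries are simultaneously within both.
    """

    library_id: str
    entries: tuple[LibraryEntry, ...] = ()
    rt_tol: float = DEFAULT_RT_TOL
    mz_tol: float = DEFAULT_MZ_TOL

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        ids = [e.entry_id for e in entries]
        if len(set(ids)) != len(ids):
            raise InvariantError("entry_ids must be unique within a library")

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, entry_id: int) -> LibraryEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)


def build_library(
    feature_sets: Sequence[tuple[str, Sequence[ChromatographicFeature]]],
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    library_id: str = "library",
) -> TargetLibrary:
    """Merge characterized features from several sources into one library.

    Any two features within both ``rt_tol`` and ``mz_tol`` of each other
    collapse to a single entry; the representative with the largest peak
    area (and its MS2 spectrum) is kept.  Entry ids are assigned in
    retention-time order starting at 1.
    """
    if not rt_tol > 0 or not mz_tol > 0:
        raise ParameterError("rt_tol and mz_tol must be > 0")

    # candidates sorted by area descending: each keeps itself unless it
    # duplicates an already-kept, higher-area feature
    candidates = [
        (feat, source)
        for source, feats in feature_sets
        for feat in feats
    ]
    candidates.sort(key=lambda c: (-c[0].area, c[0].rt_apex, c[0].mz))
    kept: list[tuple[ChromatographicFeature, str]] = []
    for feat, source in candidates:
        dup = any(
            abs(feat.rt_apex - k.rt_apex) <= rt_tol and abs(feat.mz - k.mz) <= mz_tol
            for k, _ in kept
        )
        if not dup:
            kept.append((feat, source))
    kept.sort(key=lambda c: (c[0].rt_apex, c[0].mz))
    entries = tuple(
        LibraryEntry(
            entry_id=i + 1,
            rt=feat.rt_apex,
            mz=feat.mz,
            ms2=feat.ms2,
            source=source,
            area=feat.area,
        )
        for i, (feat, source) in enumerate(kept)
    )
    return TargetLibrary(library_id=library_id, entries=entries, rt_tol=rt_tol, mz_tol=mz_tol)


def query(
    library: TargetLibrary,
    mz: float,
    rt: float,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> list[LibraryEntry]:
    """All entries within both tolerances, sorted by mass error then RT error."""
    if not rt_tol > 0 or not mz_tol > 0:
        raise ParameterError("rt_tol and mz_tol must be > 0")
    matches = [
        e
        for e in library.entries
        if abs(e.mz - mz) <= mz_tol and abs(e.rt - rt) <= rt_tol
    ]
    matches.sort(key=lambda e: (abs(e.mz - mz), abs(e.rt - rt), e.entry_id))
    return matches


# The seven target-molecule characterizations printed for the Erythropodium
# caribaeorum (EC) extract: (name, RT min, observed mass amu).  The full
# 82-member screening library was never tabulated; see synthetic_data for a
# synthetic stand-in at that scale.
EC_CHARACTERIZATIONS: tuple[tuple[str, float, float], ...] = (
    ("desmethyleleutherobin", 1.69, 643.3),
    ("eleutherobin", 2.04, 657.2),
    ("erythrolide A", 2.05, 419.2),
    ("erythrolide B", 2.16, 479.1),
    ("compound 41", 2.48, 534.4),
    ("compound 47", 2.59, 620.3),
    ("compound 53", 2.75, 706.3),
)


def ec_reference_library(
    rt_tol: float = DEFAULT_RT_TOL, mz_tol: float = DEFAULT_MZ_TOL
) -> TargetLibrary:
    """The seven-entry Erythropodium caribaeorum (EC) reference library.

    Built from the published RT/mass characterizations of the coral
    extract's known metabolites (no MS/MS spectra).
    """
    feats = [
        (
            name,
            ChromatographicFeature(
                mz=mz, rt_apex=rt, rt_start=rt, rt_end=rt, area=0.0, height=0.0
            ),
        )
        for name, rt, mz in EC_CHARACTERIZATIONS
    ]
    lib = build_library(
        [(name, [f]) for name, f in feats],
        rt_tol=rt_tol,
        mz_tol=mz_tol,
        library_id="EC-reference",
    )
    # re-attach names by coordinates (build_library works on anonymous features)
    named = []
    for e in lib.entries:
        name = next(n for n, rt, mz in EC_CHARACTERIZATIONS if rt == e.rt and mz == e.mz)
        named.append(replace(e, name=name))
    return TargetLibrary(
        library_id=lib.library_id, entries=tuple(named), rt_tol=rt_tol, mz_tol=mz_tol
    )


# ---------------------------------------------------------------------------
# Serialization


def _spectrum_to_dict(s: MassSpectrum) -> dict:
    return {
        "ms_level": s.ms_level,
        "retention_time": s.retention_time,
        "precursor_mz": s.precursor_mz,
        "peaks": [[m, i] for m, i in s.peaks],
    }


def _spectrum_from_dict(d: dict) -> MassSpectrum:
    return MassSpectrum(
        ms_level=int(d["ms_level"]),
        retention_time=float(d["retention_time"]),
        precursor_mz=None if d.get("precursor_mz") is None else float(d["precursor_mz"]),
        peaks=tuple((float(m), float(i)) for m, i in d["peaks"]),
    )


def write_json(library: TargetLibrary, path) -> None:
    """Write the lossless native JSON form of a library."""
    doc = {
        "library_id": library.library_id,
        "rt_tol": library.rt_tol,
        "mz_tol": library.mz_tol,
        "entries": [
            {
                "entry_id": e.entry_id,
                "name": e.name,
                "rt": e.rt,
                "mz": e.mz,
                "source": e.source,
                "area": e.area,
                "ms2": None if e.ms2 is None else _spectrum_to_dict(e.ms2),
            }
            for e in library.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_json(path) -> TargetLibrary:
    try:
        with open(path) as fh:
            doc = json.load(fh)
        entries = tuple(
            LibraryEntry(
                entry_id=int(d["entry_id"]),
                name=d.get("name"),
                rt=float(d["rt"]),
                mz=float(d["mz"]),
                source=d.get("source", ""),
                area=float(d.get("area", 0.0)),
                ms2=None if d.get("ms2") is None else _spectrum_from_dict(d["ms2"]),
            )
            for d in doc["entries"]
        )
        return TargetLibrary(
            library_id=doc["library_id"],
            entries=entries,
            rt_tol=float(doc["rt_tol"]),
            mz_tol=float(doc["mz_tol"]),
        )
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed library JSON {path}: {exc}") from exc


def write_msp(library: TargetLibrary, path) -> None:
    """Write a library as NIST-style MSP text records.

    Each record carries Name, ENTRYID, PRECURSORMZ, RETENTIONTIME,
    Comment (source), AREA, and ``Num Peaks`` followed by tab-separated
    peak lines (entries without MS2 get ``Num Peaks: 0``).
    """
    with open(path, "w") as fh:
        fh.write(f"# platescreen MSP library: {library.library_id} "
                 f"rt_tol={library.rt_tol!r} mz_tol={library.mz_tol!r}\n")
        for e in library.entries:
            fh.write(f"Name: {e.name if e.name is not None else f'entry_{e.entry_id}'}\n")
            fh.write(f"ENTRYID: {e.entry_id}\n")
            fh.write(f"PRECURSORMZ: {e.mz!r}\n")
            fh.write(f"RETENTIONTIME: {e.rt!r}\n")
            if e.source:
                fh.write(f"Comment: {e.source}\n")
            fh.write(f"AREA: {e.area!r}\n")
            peaks = e.ms2.peaks if e.ms2 is not None else ()
            fh.write(f"Num Peaks: {len(peaks)}\n")
            for m, i in peaks:
                fh.write(f"{m!r}\t{i!r}\n")
            fh.write("\n")


def read_msp(path) -> TargetLibrary:
    """Read an MSP library written by :func:`write_msp`.

    Foreign MSP files are accepted as long as each record has Name,
    PRECURSORMZ, RETENTIONTIME, and Num Peaks; ids are assigned by record
    order when ENTRYID is absent.
    """
    header = {"rt_tol": DEFAULT_RT_TOL, "mz_tol": DEFAULT_MZ_TOL, "library_id": "msp"}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines and lines[0].startswith("# platescreen MSP library:"):
        parts = lines[0].split()
        header["library_id"] = parts[4]
        for p in parts[5:]:
            k, _, v = p.partition("=")
            header[k] = float(v)
        lines = lines[1:]

    entries: list[LibraryEntry] = []
    record: dict = {}
    peaks: list[tuple[float, float]] = []
    expecting = 0
    rec_index = 0

    def _flush():
        nonlocal record, peaks, rec_index
        if not record:
            return
        rec_index += 1
        if "num_peaks" not in record:
            raise FormatError(f"MSP record {rec_index} missing 'Num Peaks'")
        for key in ("PRECURSORMZ", "RETENTIONTIME"):
            if key not in record:
                raise FormatError(f"MSP record {rec_index} missing '{key}'")
        if len(peaks) != record["num_peaks"]:
            raise FormatError(
                f"MSP record {rec_index}: expected {record['num_peaks']} peaks, "
                f"found {len(peaks)}"
            )
        mz = float(record["PRECURSORMZ"])
        rt = float(record["RETENTIONTIME"])
        ms2 = None
        if peaks:
            pk = tuple(sorted(peaks))
            ms2 = MassSpectrum(ms_level=2, retention_time=rt, precursor_mz=mz, peaks=pk)
        entry_id = int(record.get("ENTRYID", rec_index))
        name = record.get("Name")
        if name == f"entry_{entry_id}":  # placeholder for anonymous entries
            name = None
        entries.append(
            LibraryEntry(
                entry_id=entry_id,
                name=name,
                rt=rt,
                mz=mz,
                source=record.get("Comment", ""),
                area=float(record.get("AREA", 0.0)),
                ms2=ms2,
            )
        )
        record, peaks = {}, []

    try:
        for line in lines:
            line = line.strip()
            if not line:
                _flush()
                expecting = 0
                continue
            if expecting > 0:
                cols = line.replace("\t", " ").split()
                peaks.append((float(cols[0]), float(cols[1])))
                expecting -= 1
                continue
            key, sep, value = line.partition(":")
            if not sep:
                raise FormatError(f"MSP record {rec_index + 1}: unparseable line {line!r}")
            key, value = key.strip(), value.strip()
            if key.lower() == "num peaks":
                record["num_peaks"] = int(value)
                expecting = int(value)
            else:
                record[key] = value
        _flush()
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed MSP record {rec_index + 1} in {path}: {exc}") from exc
    entries.sort(key=lambda e: e.entry_id)
    return TargetLibrary(
        library_id=str(header["library_id"]),
        entries=tuple(entries),
        rt_tol=float(header["rt_tol"]),
        mz_tol=float(header["mz_tol"]),
    )
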