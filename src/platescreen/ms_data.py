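"""Core LC-MS data model, mzML reading, and feature extraction.

Conventions: retention times are minutes throughout (the 6-minute gradient
of the standard screening method makes seconds awkward), masses are the
observed "amu" values with no adduct or charge inference, and intensities
are arbitrary detector counts.  Feature areas are therefore counts*min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvariantError, ParameterError, UnsupportedModeError

__all__ = [
    "MassSpectrum",
    "LcmsRun",
    "ChromatographicFeature",
    "read_mzml",
    "extract_features",
    "read_feature_csv",
    "write_feature_csv",
    "FEATURE_CSV_COLUMNS",
]


@dataclass(frozen=True)
class MassSpectrum:
    """One centroided MS1 or MS2 scan.

    Parameters
    ----------
    ms_level : int
        1 for a survey scan, 2 for a fragmentation (MS/MS) scan.
    retention_time : float
        Scan time in minutes, >= 0.
    peaks : tuple of (mz, intensity)
        Centroid peak list, m/z strictly increasing, intensities >= 0.
    precursor_mz : float, optional
        Isolated precursor m/z; required (and > 0) iff ``ms_level == 2``.
    """

    ms_level: int
    retention_time: float
    peaks: tuple[tuple[float, float], ...]
    precursor_mz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ms_level not in (1, 2):
            raise InvariantError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.retention_time < 0:
            raise InvariantError(f"retention_time must be >= 0, got {self.retention_time}")
        if self.ms_level == 2:
            if self.precursor_mz is None or not self.precursor_mz > 0:
                raise InvariantError("MS2 spectrum requires precursor_mz > 0")
        peaks = tuple((float(m), float(i)) for m, i in self.peaks)
        object.__setattr__(self, "peaks", peaks)
        mzs = [m for m, _ in peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise InvariantError("peak m/z values must be strictly increasing")
        if any(i < 0 for _, i in peaks):
            raise InvariantError("peak intensities must be >= 0")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks], dtype=float)

    def base_peak(self) -> tuple[float, float]:
        """(m/z, intensity) of the most intense peak."""
        if not self.peaks:
            raise InvariantError("empty spectrum has no base peak")
        return max(self.peaks, key=lambda p: p[1])


@dataclass(frozen=True)
class LcmsRun:
    """A single chromatographic run: spectra ordered by retention time."""

    run_id: str
    spectra: tuple[MassSpectrum, ...] = ()
    gradient_length: float = 6.0  # minutes; the standard 5%->100% ACN gradient

    def __post_init__(self) -> None:
        if not self.gradient_length > 0:
            raise InvariantError("gradient_length must be > 0")
        spectra = tuple(self.spectra)
        object.__setattr__(self, "spectra", spectra)
        rts = [s.retention_time for s in spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise InvariantError("spectra must be sorted by retention_time")

    def ms1_spectra(self) -> list[MassSpectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_spectra(self) -> list[MassSpectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass(frozen=True)
class ChromatographicFeature:
    """An eluting ion: an extracted-ion trace reduced to apex/area summary.

    ``mz`` is the intensity-weighted mean m/z of the trace, ``area`` the
    trapezoidal integral of intensity over time (counts*min), and ``ms2``
    an optional linked fragmentation spectrum of the same precursor.
    """

    mz: float
    rt_apex: float
    rt_start: float
    rt_end: float
    area: float
    height: float
    ms2: Optional[MassSpectrum] = None

    def __post_init__(self) -> None:
        if not (self.rt_start <= self.rt_apex <= self.rt_end):
            raise InvariantError(
                f"require rt_start <= rt_apex <= rt_end, got "
                f"{self.rt_start}, {self.rt_apex}, {self.rt_end}"
            )
        if self.area < 0:
            raise InvariantError(f"area must be >= 0, got {self.area}")
        if self.height < 0:
            raise InvariantError(f"height must be >= 0, got {self.height}")
        if self.ms2 is not None and self.ms2.ms_level != 2:
            raise InvariantError("linked spectrum must be an MS2 scan")


FEATURE_CSV_COLUMNS = ["mz", "rt_apex", "rt_start", "rt_end", "area", "height"]

# PSI-MS controlled-vocabulary accessions understood by the mzML reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"

_TIME_UNIT_TO_MINUTES = {
    "minute": 1.0,
    "min": 1.0,
    "second": 1 / 60.0,
    "s": 1 / 60.0,
    "millisecond": 1 / 60000.0,
    "ms": 1 / 60000.0,
    "": 1.0,  # bare value: assume minutes, the toolkit's native unit
}


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, dict]:
    """accession -> {value, unit} for direct cvParam children."""
    out = {}
    for child in element:
        if _localname(child.tag) == "cvParam":
            out[child.get("accession", "")] = {
                "value": child.get("value", ""),
                "unit": child.get("unitName", ""),
            }
    return out


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib

    params = _cv_params(bda)
    if _ACC_FLOAT64 in params:
        dtype = "<f8"
    elif _ACC_FLOAT32 in params:
        dtype = "<f4"
    else:
        raise FormatError("binary array lacks a float precision cvParam")
    text = ""
    for child in bda:
        if _localname(child.tag) == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(spec_el) -> MassSpectrum:
    params = _cv_params(spec_el)
    if _ACC_PROFILE in params:
        raise UnsupportedModeError("profile-mode data; only centroided spectra are supported")
    if _ACC_MS_LEVEL not in params:
        raise FormatError("spectrum lacks an 'ms level' cvParam")
    ms_level = int(params[_ACC_MS_LEVEL]["value"])

    rt = None
    precursor = None
    mzs = ints = None
    for el in spec_el.iter():
        name = _localname(el.tag)
        if name == "scan":
            sp = _cv_params(el)
            if _ACC_SCAN_START in sp:
                unit = sp[_ACC_SCAN_START]["unit"]
                if unit not in _TIME_UNIT_TO_MINUTES:
                    raise FormatError(f"unrecognized scan time unit {unit!r}")
                rt = float(sp[_ACC_SCAN_START]["value"]) * _TIME_UNIT_TO_MINUTES[unit]
        elif name == "selectedIon":
            sp = _cv_params(el)
            if _ACC_SELECTED_MZ in sp:
                precursor = float(sp[_ACC_SELECTED_MZ]["value"])
        elif name == "binaryDataArray":
            sp = _cv_params(el)
            if _ACC_MZ_ARRAY in sp:
                mzs = _decode_binary_array(el)
            elif _ACC_INTENSITY_ARRAY in sp:
                ints = _decode_binary_array(el)
    if rt is None:
        raise FormatError("spectrum lacks a scan start time")
    if mzs is None or ints is None:
        raise FormatError("spectrum lacks m/z or intensity binary arrays")
    if len(mzs) != len(ints):
        raise FormatError("m/z and intensity arrays differ in length")
    if ms_level == 2 and precursor is None:
        raise FormatError("MS2 scan lacks a selected precursor m/z")
    order = np.argsort(mzs, kind="stable")
    return MassSpectrum(
        ms_level=ms_level,
        retention_time=rt,
        peaks=tuple(zip(mzs[order].tolist(), ints[order].tolist())),
        precursor_mz=precursor if ms_level == 2 else None,
    )


def read_mzml(path) -> LcmsRun:
    """Read a centroided mzML file into an :class:`LcmsRun`.

    The reader is accession-driven (it ignores XML namespaces and cvParam
    spelling) and handles 32/64-bit float peak arrays, zlib or no
    compression, and scan times in seconds or minutes — retention times
    are always converted to minutes.  Profile-mode spectra raise
    :class:`UnsupportedModeError`; other malformed content raises
    :class:`FormatError` naming the offending scan.
    """
    import os
    import xml.etree.ElementTree as ET

    try:
        tree = ET.parse(str(path))
    except (ET.ParseError, OSError) as exc:
        raise FormatError(f"cannot parse mzML file {path}: {exc}") from exc

    spectra: list[MassSpectrum] = []
    spectrum_elements = [
        el for el in tree.getroot().iter() if _localname(el.tag) == "spectrum"
    ]
    for idx, spec_el in enumerate(spectrum_elements):
        sid = spec_el.get("id", f"index {idx}")
        try:
            spectra.append(_parse_spectrum(spec_el))
        except UnsupportedModeError as exc:
            raise UnsupportedModeError(f"scan {sid!r}: {exc}") from exc
        except (FormatError, InvariantError, ValueError, TypeError) as exc:
            raise FormatError(f"malformed mzML scan {sid!r}: {exc}") from exc
    spectra.sort(key=lambda s: s.retention_time)
    run_id = os.path.splitext(os.path.basename(str(path)))[0]
    return LcmsRun(run_id=run_id, spectra=tuple(spectra))


def extract_features(
    run: LcmsRun,
    mz_tol: float = 0.3,
    min_height: float = 0.0,
    min_scans: int = 3,
) -> list[ChromatographicFeature]:
    """Group MS1 peaks into extracted-ion traces and reduce them to features.

    Peaks are chained across consecutive MS1 scans when within ``mz_tol``
    of a trace's running intensity-weighted mean m/z; a trace ends at the
    first MS1 scan with no matching peak.  Traces with at least
    ``min_scans`` points and apex height >= ``min_height`` become features,
    with area by trapezoidal integration.  MS2 scans are attached to the
    feature nearest in precursor m/z (within ``mz_tol``) whose RT window
    contains the scan.

    The defaults suit a unit-resolution ion trap on a 6-minute gradient.
    """
    if not mz_tol > 0:
        raise ParameterError(f"mz_tol must be > 0, got {mz_tol}")
    if min_scans < 1:
        raise ParameterError(f"min_scans must be >= 1, got {min_scans}")

    ms1 = run.ms1_spectra()

    # each trace: dict with lists of (rt, mz, intensity) plus running weighted mean
    open_traces: list[dict] = []
    closed: list[dict] = []

    for scan in ms1:
        peaks = list(scan.peaks)
        used = [False] * len(peaks)
        still_open = []
        for tr in open_traces:
            best_j, best_d = -1, None
            for j, (mz, inten) in enumerate(peaks):
                if used[j]:
                    continue
                d = abs(mz - tr["mean_mz"])
                if d <= mz_tol and (best_d is None or d < best_d):
                    best_j, best_d = j, d
            if best_j >= 0:
                mz, inten = peaks[best_j]
                used[best_j] = True
                tr["points"].append((scan.retention_time, mz, inten))
                w = tr["weight"] + inten
                if w > 0:
                    tr["mean_mz"] = (tr["mean_mz"] * tr["weight"] + mz * inten) / w
                    tr["weight"] = w
                still_open.append(tr)
            else:
                closed.append(tr)
        open_traces = still_open
        for j, (mz, inten) in enumerate(peaks):
            if not used[j]:
                open_traces.append(
                    {"points": [(scan.retention_time, mz, inten)], "mean_mz": mz,
                     "weight": inten if inten > 0 else 0.0}
                )
    closed.extend(open_traces)

    features: list[ChromatographicFeature] = []
    for tr in closed:
        pts = tr["points"]
        if len(pts) < min_scans:
            continue
        rts = np.array([p[0] for p in pts])
        mzs = np.array([p[1] for p in pts])
        ints = np.array([p[2] for p in pts])
        height = float(ints.max())
        if height < min_height:
            continue
        apex = int(np.argmax(ints))
        total = ints.sum()
        mean_mz = float((mzs * ints).sum() / total) if total > 0 else float(mzs.mean())
        area = float(np.trapezoid(ints, rts))
        features.append(
            ChromatographicFeature(
                mz=mean_mz,
                rt_apex=float(rts[apex]),
                rt_start=float(rts[0]),
                rt_end=float(rts[-1]),
                area=area,
                height=height,
            )
        )
    features.sort(key=lambda f: (f.rt_apex, f.mz))

    # attach MS2 scans: nearest feature by precursor m/z within tolerance,
    # restricted to features whose RT window contains the scan
    attached: dict[int, tuple[float, MassSpectrum]] = {}
    for scan in run.ms2_spectra():
        best_i, best_d = -1, None
        for i, f in enumerate(features):
            if not (f.rt_start <= scan.retention_time <= f.rt_end):
                continue
            d = abs(scan.precursor_mz - f.mz)
            if d <= mz_tol and (best_d is None or d < best_d):
                best_i, best_d = i, d
        if best_i >= 0 and (best_i not in attached or best_d < attached[best_i][0]):
            attached[best_i] = (best_d, scan)
    for i, (_, scan) in attached.items():
        features[i] = replace(features[i], ms2=scan)
    return features


def _ms2_to_text(s: MassSpectrum) -> str:
    return ";".join(f"{m!r}:{i!r}" for m, i in s.peaks)


def _ms2_from_text(text: str, precursor_mz: float, rt: float) -> MassSpectrum:
    peaks = []
    for token in text.split(";"):
        m, _, i = token.partition(":")
        peaks.append((float(m), float(i)))
    return MassSpectrum(ms_level=2, retention_time=rt, precursor_mz=precursor_mz,
                        peaks=tuple(sorted(peaks)))


def write_feature_csv(features: Sequence[ChromatographicFeature], path) -> None:
    """Write features to CSV (columns mz, rt_apex, rt_start, rt_end, area, height).

    Floats are serialized with full (repr) precision so a read-back is
    lossless.  When any feature carries a linked MS2 spectrum, extra
    columns (ms2_precursor_mz, ms2_rt, ms2_peaks) are appended so the
    fragmentation data survives the round trip.
    """
    import csv

    with_ms2 = any(f.ms2 is not None for f in features)
    columns = list(FEATURE_CSV_COLUMNS)
    if with_ms2:
        columns += ["ms2_precursor_mz", "ms2_rt", "ms2_peaks"]
    # floats written via repr (shortest exact form) for a lossless round trip
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for f in features:
            row = [repr(v) for v in
                   (f.mz, f.rt_apex, f.rt_start, f.rt_end, f.area, f.height)]
            if with_ms2:
                if f.ms2 is None:
                    row += ["", "", ""]
                else:
                    row += [repr(f.ms2.precursor_mz), repr(f.ms2.retention_time),
                            _ms2_to_text(f.ms2)]
            writer.writerow(row)


def read_feature_csv(path) -> list[ChromatographicFeature]:
    """Read a feature CSV written by :func:`write_feature_csv`."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse feature CSV {path}: {exc}") from exc
    missing = [c for c in FEATURE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature CSV {path} missing column(s): {', '.join(missing)}")
    has_ms2 = "ms2_peaks" in df.columns
    feats = []
    for row in df.itertuples(index=False):
        ms2 = None
        if has_ms2 and isinstance(row.ms2_peaks, str) and row.ms2_peaks:
            ms2 = _ms2_from_text(row.ms2_peaks, float(row.ms2_precursor_mz),
                                 float(row.ms2_rt))
        feats.append(
            ChromatographicFeature(
                mz=float(row.mz),
                rt_apex=float(row.rt_apex),
                rt_start=float(row.rt_start),
                rt_end=float(row.rt_end),
                area=float(row.area),
                height=float(row.height),
                ms2=ms2,
            )
        )
    return feats
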