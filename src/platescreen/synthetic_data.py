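"""Seeded synthetic data: LC-MS runs, plate extract sets, titer tables.

Everything here emulates the structures the screening workflow consumes —
plate extracts containing library targets with realistic RT jitter, mass
error and log-normal intensities on top of background noise peaks, and
full-factorial titer responses with planted factor effects — so every
stage of the toolkit is testable without instruments.  All generators are
bit-reproducible given (parameters, seed).

Chromatographic peak-shape physics and isotope envelopes are not
modeled: features are emitted directly with summary statistics, and the
mzML writer samples a Gaussian elution profile only when a run-level
serialization is requested.
"""

from __future__ import annotations

import base64
import math
import struct
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence
from xml.sax.saxutils import escape, quoteattr

import numpy as np

from .errors import ParameterError
from .ms_data import ChromatographicFeature, LcmsRun, MassSpectrum
from .plate_design import FactorialDesign, ResponseTable
from .screening import PLATE_COLUMNS, PLATE_ROWS, WellExtract
from .target_library import LibraryEntry, TargetLibrary

__all__ = [
    "SpikeSpec",
    "NoiseModel",
    "simulate_extract",
    "simulate_screen_experiment",
    "simulate_factorial_response",
    "synthetic_library",
    "default_effect_model",
    "write_mzml",
    "DEFAULT_PRODUCER_WELLS",
]

# the two producing wells observed in the original 16-plate screen
DEFAULT_PRODUCER_WELLS: tuple[tuple[str, str], ...] = (
    ("plate-1-1", "D5"),
    ("plate-2-1", "B1"),
)


@dataclass(frozen=True)
class NoiseModel:
    """Background contamination for one extract.

    ``background_peaks`` is the Poisson mean number of noise features,
    drawn uniformly in ``mz_range`` (amu) and across the gradient, with
    log-normal areas (``log_mu``/``log_sigma`` on the natural-log scale).
    """

    background_peaks: float = 30.0
    mz_range: tuple[float, float] = (100.0, 1000.0)
    log_mu: float = math.log(1e4)
    log_sigma: float = 1.0
    gradient_length: float = 6.0
    seed: Optional[int] = None  # fallback when the caller passes no seed

    def __post_init__(self) -> None:
        if self.background_peaks < 0 or self.log_sigma < 0:
            raise ParameterError("noise rates must be >= 0")
        if not self.mz_range[1] > self.mz_range[0] > 0:
            raise ParameterError("mz_range must be an increasing positive interval")


@dataclass(frozen=True)
class SpikeSpec:
    """How library targets are spiked into producer wells.

    ``intensity_scale`` sets the median spiked peak area; ``rt_sigma``
    (minutes) and ``mz_sigma`` (amu) are the Gaussian measurement jitters
    applied to the library coordinates.  Defaults give clean separation
    at the standard matching tolerances (0.1 min / 0.3 amu); double the
    sigmas for a stress-test "hard mode".
    """

    targets: tuple[tuple[str, str], ...] = DEFAULT_PRODUCER_WELLS
    entry_ids: tuple[int, ...] = ()
    intensity_scale: float = 1e5
    rt_sigma: float = 0.02
    mz_sigma: float = 0.05

    def __post_init__(self) -> None:
        if not self.intensity_scale > 0:
            raise ParameterError("intensity_scale must be > 0")
        if self.rt_sigma < 0 or self.mz_sigma < 0:
            raise ParameterError("jitter sigmas must be >= 0")


def _perturb_ms2(spec: MassSpectrum, rng: np.random.Generator,
                 precursor_mz: float, rt: float) -> MassSpectrum:
    """A measurement-like copy of a fragmentation spectrum."""
    mzs = np.array([m for m, _ in spec.peaks])
    ints = np.array([i for _, i in spec.peaks])
    mzs = mzs + rng.normal(0.0, 0.01, size=mzs.size)
    ints = ints * rng.lognormal(0.0, 0.2, size=ints.size)
    order = np.argsort(mzs)
    mzs, ints = mzs[order], ints[order]
    # enforce strictly increasing m/z after jitter
    for i in range(1, mzs.size):
        if mzs[i] <= mzs[i - 1]:
            mzs[i] = mzs[i - 1] + 1e-6
    return MassSpectrum(
        ms_level=2, retention_time=rt, precursor_mz=precursor_mz,
        peaks=tuple(zip(mzs.tolist(), ints.tolist())),
    )


def _simulate_extract_rng(
    library: TargetLibrary,
    spiked_entry_ids: Sequence[int],
    noise: NoiseModel,
    spike: SpikeSpec,
    rng: np.random.Generator,
    plate_id: str,
    well: str,
) -> WellExtract:
    features: list[ChromatographicFeature] = []
    for eid in spiked_entry_ids:
        entry = library.get(eid)
        rt = max(0.0, entry.rt + rng.normal(0.0, spike.rt_sigma))
        mz = entry.mz + rng.normal(0.0, spike.mz_sigma)
        area = spike.intensity_scale * rng.lognormal(0.0, 0.3)
        width = 0.05
        ms2 = None
        if entry.ms2 is not None:
            ms2 = _perturb_ms2(entry.ms2, rng, precursor_mz=mz, rt=rt)
        features.append(
            ChromatographicFeature(
                mz=mz, rt_apex=rt, rt_start=max(0.0, rt - width), rt_end=rt + width,
                area=area, height=area / (width * math.sqrt(2 * math.pi)), ms2=ms2,
            )
        )
    n_bg = int(rng.poisson(noise.background_peaks))
    lo, hi = noise.mz_range
    for _ in range(n_bg):
        mz = float(rng.uniform(lo, hi))
        rt = float(rng.uniform(0.1, noise.gradient_length))
        area = float(rng.lognormal(noise.log_mu, noise.log_sigma))
        width = 0.05
        features.append(
            ChromatographicFeature(
                mz=mz, rt_apex=rt, rt_start=max(0.0, rt - width), rt_end=rt + width,
                area=area, height=area / (width * math.sqrt(2 * math.pi)),
            )
        )
    features.sort(key=lambda f: (f.rt_apex, f.mz))
    return WellExtract(plate_id=plate_id, well=well, features=tuple(features))


def simulate_extract(
    library: TargetLibrary,
    spiked_entry_ids: Sequence[int] = (),
    noise: NoiseModel = NoiseModel(),
    spike: SpikeSpec = SpikeSpec(),
    seed: Optional[int] = None,
    plate_id: str = "plate-1",
    well: str = "A1",
) -> WellExtract:
    """One well's extract: spiked library targets plus background noise."""
    if seed is None:
        seed = noise.seed if noise.seed is not None else 0
    rng = np.random.default_rng(seed)
    return _simulate_extract_rng(
        library, spiked_entry_ids, noise, spike, rng, plate_id, well
    )


def simulate_screen_experiment(
    library: TargetLibrary,
    producer_wells: Sequence[tuple[str, str]] = DEFAULT_PRODUCER_WELLS,
    spiked_entry_ids: Sequence[int] = (),
    noise: NoiseModel = NoiseModel(),
    spike: SpikeSpec = SpikeSpec(),
    seed: int = 0,
    n_plates: int = 16,
) -> list[WellExtract]:
    """A full subculture-screen extract set: ``n_plates`` 96-well plates.

    Producer wells receive every spiked target; all other wells carry
    background only.  Plate ids follow the enrichment/subculture naming
    ``plate-<enrichment>-<subculture>`` for 16 plates, and wells are
    generated in a fixed order so the set is reproducible per seed.
    """
    if n_plates == 16:
        plate_ids = [f"plate-{e}-{s}" for e in range(1, 5) for s in range(1, 5)]
    else:
        plate_ids = [f"plate-{i}" for i in range(1, n_plates + 1)]
    producers = set(producer_wells)
    unknown = producers - {(p, f"{r}{c}") for p in plate_ids
                           for r in PLATE_ROWS for c in PLATE_COLUMNS}
    if unknown:
        raise ParameterError(f"producer wells not on any generated plate: {unknown}")
    rng = np.random.default_rng(seed)
    extracts = []
    for pid in plate_ids:
        for row in PLATE_ROWS:
            for col in PLATE_COLUMNS:
                well = f"{row}{col}"
                spiked = spiked_entry_ids if (pid, well) in producers else ()
                extracts.append(
                    _simulate_extract_rng(library, spiked, noise, spike, rng, pid, well)
                )
    return extracts


def default_effect_model() -> dict[str, tuple[float, ...]]:
    """Planted factor effects mirroring the observed TB optimization trends.

    Titers rise with tryptone, fall with yeast extract, and peak at mid
    glycerol; the best combination is 2.4x the all-mid reference, inside
    the 1.3-5.23x band the original optimization reported.
    """
    return {
        "tryptone": (0.6, 1.0, 1.5),
        "yeast_extract": (1.6, 1.0, 0.5),
        "glycerol": (0.8, 1.0, 0.9),
    }


def simulate_factorial_response(
    design: FactorialDesign,
    effect_model: Optional[dict[str, Sequence[float]]] = None,
    noise_sigma: float = 0.1,
    seed: int = 0,
    strains: Sequence[str] = ("E1-1D5g", "E1-1D5i", "E1-1D5j"),
    replicates: int = 2,
    baseline: float = 1e5,
) -> ResponseTable:
    """Titer table: baseline x per-factor level multipliers x log-normal noise.

    ``effect_model`` maps factor name -> one multiplier per level (in
    design level order); factors not named get multiplier 1 at every
    level.  Defaults mimic three producer strains cultured in duplicate.
    """
    if effect_model is None:
        effect_model = default_effect_model()
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    level_index = {
        name: {lv: i for i, lv in enumerate(levels)} for name, levels in design.factors
    }
    for name, mults in effect_model.items():
        if name in level_index and len(mults) != len(level_index[name]):
            raise ParameterError(f"effect model for {name!r} needs one multiplier per level")
    rng = np.random.default_rng(seed)
    records = []
    for fid, combo in design.formulations:
        mult = 1.0
        for name, value in combo:
            if name in effect_model:
                mult *= effect_model[name][level_index[name][value]]
        for strain in strains:
            for rep in range(1, replicates + 1):
                noise = rng.lognormal(0.0, noise_sigma) if noise_sigma > 0 else 1.0
                records.append((fid, strain, rep, baseline * mult * noise))
    return ResponseTable(records=tuple(records), reference_id=design.reference_id)


# ---------------------------------------------------------------------------
# Synthetic 82-entry library


def _random_ms2(rng: np.random.Generator, precursor_mz: float, rt: float) -> MassSpectrum:
    n = int(rng.integers(8, 16))
    mzs = np.sort(rng.uniform(50.0, precursor_mz - 5.0, size=n))
    mzs += np.arange(n) * 1e-6  # break exact ties
    ints = rng.lognormal(math.log(1e3), 1.0, size=n)
    return MassSpectrum(
        ms_level=2, retention_time=rt, precursor_mz=precursor_mz,
        peaks=tuple(zip(mzs.tolist(), ints.tolist())),
    )


def synthetic_library(
    seed: int = 0,
    n_entries: int = 82,
    rt_tol: float = 0.1,
    mz_tol: float = 0.3,
    gradient_length: float = 6.0,
) -> TargetLibrary:
    """A synthetic stand-in for the 82-member coral metabolite library.

    The real library was characterized but never tabulated, so this
    generator plants the three printed 3-hydroxybutyrate oligomer
    characterizations (compounds 41, 47, 53) at their published RT/mass
    coordinates and fills the rest with random metabolites, every entry
    carrying a synthetic MS/MS spectrum.  No two entries fall within both
    build tolerances (the dedup guarantee), and ids are assigned in RT
    order.
    """
    planted = [
        ("compound 41", 2.48, 534.4),
        ("compound 47", 2.59, 620.3),
        ("compound 53", 2.75, 706.3),
    ]
    if n_entries < len(planted):
        raise ParameterError(f"n_entries must be >= {len(planted)}")
    rng = np.random.default_rng(seed)
    coords: list[tuple[Optional[str], float, float]] = [
        (name, rt, mz) for name, rt, mz in planted
    ]
    while len(coords) < n_entries:
        rt = float(rng.uniform(0.3, gradient_length - 0.2))
        mz = float(rng.uniform(150.0, 900.0))
        if any(abs(rt - r) <= 2 * rt_tol and abs(mz - m) <= 2 * mz_tol
               for _, r, m in coords):
            continue
        coords.append((None, rt, mz))
    coords.sort(key=lambda c: (c[1], c[2]))
    entries = tuple(
        LibraryEntry(
            entry_id=i + 1,
            name=name,
            rt=rt,
            mz=mz,
            ms2=_random_ms2(rng, precursor_mz=mz, rt=rt),
            source="synthetic",
            area=float(rng.lognormal(math.log(1e5), 0.5)),
        )
        for i, (name, rt, mz) in enumerate(coords)
    )
    return TargetLibrary(
        library_id=f"synthetic-{n_entries}", entries=entries, rt_tol=rt_tol, mz_tol=mz_tol
    )


# ---------------------------------------------------------------------------
# Minimal centroided-mzML writer


def _encode_array(values: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: Optional[tuple[str, str, str]] = None) -> str:
    s = (f'<cvParam cvRef="MS" accession="{accession}" name={quoteattr(name)} '
         f'value={quoteattr(value)}')
    if unit is not None:
        acc, uname, ref = unit
        s += f' unitAccession="{acc}" unitName={quoteattr(uname)} unitCvRef="{ref}"'
    return s + "/>"


def write_mzml(run: LcmsRun, path, mode: str = "centroid") -> None:
    """Serialize a run as minimal centroided mzML (64-bit floats, uncompressed).

    Written files round-trip bit-for-bit through :func:`platescreen.read_mzml`.
    ``mode='profile'`` marks spectra as profile data (useful only for
    exercising the reader's unsupported-mode rejection).
    """
    if mode not in ("centroid", "profile"):
        raise ParameterError(f"mode must be 'centroid' or 'profile', got {mode!r}")
    mode_cv = (
        _cv("MS:1000127", "centroid spectrum")
        if mode == "centroid"
        else _cv("MS:1000128", "profile spectrum")
    )
    minute_unit = ("UO:0000031", "minute", "UO")
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>',
        "</cvList>",
        f"<run id={quoteattr(run.run_id)}>",
        f'<spectrumList count="{len(run.spectra)}">',
    ]
    for i, spec in enumerate(run.spectra):
        mzs = [m for m, _ in spec.peaks]
        ints = [v for _, v in spec.peaks]
        mz_b64 = _encode_array(mzs)
        int_b64 = _encode_array(ints)
        lines += [
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mzs)}">',
            _cv("MS:1000511", "ms level", str(spec.ms_level)),
            mode_cv,
            '<scanList count="1">',
            "<scan>",
            _cv("MS:1000016", "scan start time", repr(spec.retention_time), minute_unit),
            "</scan>",
            "</scanList>",
        ]
        if spec.ms_level == 2:
            lines += [
                '<precursorList count="1">',
                "<precursor>",
                '<selectedIonList count="1">',
                "<selectedIon>",
                _cv("MS:1000744", "selected ion m/z", repr(spec.precursor_mz),
                    ("MS:1000040", "m/z", "MS")),
                "</selectedIon>",
                "</selectedIonList>",
                "</precursor>",
                "</precursorList>",
            ]
        lines += [
            '<binaryDataArrayList count="2">',
            f'<binaryDataArray encodedLength="{len(mz_b64)}">',
            _cv("MS:1000523", "64-bit float"),
            _cv("MS:1000576", "no compression"),
            _cv("MS:1000514", "m/z array", unit=("MS:1000040", "m/z", "MS")),
            f"<binary>{mz_b64}</binary>",
            "</binaryDataArray>",
            f'<binaryDataArray encodedLength="{len(int_b64)}">',
            _cv("MS:1000523", "64-bit float"),
            _cv("MS:1000576", "no compression"),
            _cv("MS:1000515", "intensity array",
                unit=("MS:1000131", "number of detector counts", "MS")),
            f"<binary>{int_b64}</binary>",
            "</binaryDataArray>",
            "</binaryDataArrayList>",
            "</spectrum>",
        ]
    lines += ["</spectrumList>", "</run>", "</mzML>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
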