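"""Spectrum/run/feature invariants, mzML round trips, feature extraction."""

import math

import numpy as np
import pytest

import platescreen as ps
from platescreen.errors import (
    FormatError,
    InvariantError,
    ParameterError,
    UnsupportedModeError,
)

from conftest import random_features


class TestInvariants:
    def test_peak_mz_must_strictly_increase(self):
        with pytest.raises(InvariantError):
            ps.MassSpectrum(1, 1.0, ((200.0, 1.0), (100.0, 1.0)))
        with pytest.raises(InvariantError):
            ps.MassSpectrum(1, 1.0, ((100.0, 1.0), (100.0, 1.0)))

    def test_negative_intensity_rejected(self):
        with pytest.raises(InvariantError):
            ps.MassSpectrum(1, 1.0, ((100.0, -1.0),))

    def test_ms2_requires_positive_precursor(self):
        with pytest.raises(InvariantError):
            ps.MassSpectrum(2, 1.0, ((100.0, 1.0),))
        with pytest.raises(InvariantError):
            ps.MassSpectrum(2, 1.0, ((100.0, 1.0),), precursor_mz=0.0)

    def test_run_spectra_must_be_rt_sorted(self):
        a = ps.MassSpectrum(1, 2.0, ())
        b = ps.MassSpectrum(1, 1.0, ())
        with pytest.raises(InvariantError):
            ps.LcmsRun("r", spectra=(a, b))

    def test_feature_rt_ordering_enforced(self):
        with pytest.raises(InvariantError):
            ps.ChromatographicFeature(mz=100, rt_apex=0.5, rt_start=1.0,
                                      rt_end=2.0, area=1, height=1)


def _gaussian_run(height=1e5, mu=2.0, sigma=0.05, n_scans=21, mz=400.0):
    # odd n_scans puts one sample exactly at the apex
    rts = np.linspace(mu - 4 * sigma, mu + 4 * sigma, n_scans)
    spectra = tuple(
        ps.MassSpectrum(1, float(t), ((mz, float(height * math.exp(-((t - mu) ** 2) / (2 * sigma**2)))),))
        for t in rts
    )
    return ps.LcmsRun("gauss", spectra=spectra)


class TestExtractFeatures:
    def test_empty_run_gives_no_features(self):
        assert ps.extract_features(ps.LcmsRun("empty")) == []

    def test_gaussian_trace_area_matches_closed_form(self):
        # one ion tracing a sampled Gaussian: trapezoid vs analytic integral
        height, sigma = 1e5, 0.05
        run = _gaussian_run(height=height, sigma=sigma)
        feats = ps.extract_features(run, mz_tol=0.3, min_height=0, min_scans=3)
        assert len(feats) == 1
        analytic = height * sigma * math.sqrt(2 * math.pi)
        assert feats[0].area == pytest.approx(analytic, rel=0.02)
        assert feats[0].rt_apex == pytest.approx(2.0, abs=0.05)
        assert feats[0].height == pytest.approx(height, rel=1e-6)

    def test_coeluting_ions_one_amu_apart_stay_separate(self):
        # brute force over all peak pairs: no pair within 0.3 amu -> 2 traces
        rts = np.linspace(1.0, 1.5, 10)
        spectra = tuple(
            ps.MassSpectrum(1, float(t), ((300.0, 1e4), (301.0, 2e4)))
            for t in rts
        )
        run = ps.LcmsRun("pair", spectra=spectra)
        feats = ps.extract_features(run, mz_tol=0.3, min_height=0, min_scans=3)
        assert len(feats) == 2
        assert sorted(round(f.mz) for f in feats) == [300, 301]

    def test_mz_tol_must_be_positive(self):
        with pytest.raises(ParameterError):
            ps.extract_features(ps.LcmsRun("r"), mz_tol=0.0)

    def test_deterministic(self):
        run = _gaussian_run()
        assert ps.extract_features(run) == ps.extract_features(run)

    def test_area_conservation_against_total_ion_current(self):
        rng = np.random.default_rng(5)
        spectra = []
        for t in np.linspace(0.5, 2.5, 40):
            mzs = np.sort(rng.uniform(100, 500, size=6))
            mzs += np.arange(6) * 1e-5
            ints = rng.lognormal(np.log(1e4), 1.0, size=6)
            spectra.append(ps.MassSpectrum(1, float(t), tuple(zip(mzs.tolist(), ints.tolist()))))
        run = ps.LcmsRun("noise", spectra=tuple(spectra))
        feats = ps.extract_features(run, mz_tol=0.3, min_height=0, min_scans=1)
        rts = [s.retention_time for s in spectra]
        tic = [sum(i for _, i in s.peaks) for s in spectra]
        total = np.trapezoid(tic, rts)
        assert sum(f.area for f in feats) <= total + 1e-9

    def test_locality_removing_outside_peaks_preserves_area(self):
        run = _gaussian_run()
        feats = ps.extract_features(run, mz_tol=0.3, min_scans=3)
        f = feats[0]
        trimmed = ps.LcmsRun(
            "trimmed",
            spectra=tuple(s for s in run.spectra
                          if f.rt_start <= s.retention_time <= f.rt_end),
        )
        feats2 = ps.extract_features(trimmed, mz_tol=0.3, min_scans=3)
        assert feats2[0].area == pytest.approx(f.area, rel=1e-12)

    def test_ms2_attached_by_precursor_and_rt_containment(self):
        base = _gaussian_run(mz=400.0)
        ms2 = ps.MassSpectrum(2, 2.0, ((120.0, 5.0), (250.0, 9.0)), precursor_mz=400.1)
        spectra = tuple(sorted(base.spectra + (ms2,), key=lambda s: s.retention_time))
        run = ps.LcmsRun("withms2", spectra=spectra)
        feats = ps.extract_features(run, mz_tol=0.3)
        assert len(feats) == 1
        assert feats[0].ms2 == ms2


class TestMzmlRoundTrip:
    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        spectra = []
        for i, t in enumerate(np.linspace(0.5, 3.0, 8)):
            mzs = np.sort(rng.uniform(100, 800, size=5)) + np.arange(5) * 1e-6
            ints = rng.lognormal(np.log(1e4), 1.0, size=5)
            spectra.append(ps.MassSpectrum(1, float(t), tuple(zip(mzs.tolist(), ints.tolist()))))
            if i == 3:
                spectra.append(
                    ps.MassSpectrum(2, float(t) + 0.001,
                                    ((150.123456789, 7.0), (300.5, 2.0)),
                                    precursor_mz=float(mzs[0]))
                )
        run = ps.LcmsRun("rt", spectra=tuple(spectra))
        path = tmp_path / "rt.mzml"
        ps.write_mzml(run, path)
        back = ps.read_mzml(path)
        assert back.spectra == run.spectra

    def test_empty_run_reads_back_empty(self, tmp_path):
        path = tmp_path / "empty.mzml"
        ps.write_mzml(ps.LcmsRun("empty"), path)
        assert ps.read_mzml(path).spectra == ()

    def test_profile_mode_rejected(self, tmp_path):
        run = ps.LcmsRun("p", spectra=(ps.MassSpectrum(1, 1.0, ((100.0, 1.0),)),))
        path = tmp_path / "p.mzml"
        ps.write_mzml(run, path, mode="profile")
        with pytest.raises(UnsupportedModeError):
            ps.read_mzml(path)

    def test_ms2_without_precursor_rejected(self, tmp_path):
        run = ps.LcmsRun("m", spectra=(
            ps.MassSpectrum(2, 1.0, ((100.0, 1.0),), precursor_mz=250.0),
        ))
        path = tmp_path / "m.mzml"
        ps.write_mzml(run, path)
        text = path.read_text()
        start = text.index("<precursorList")
        end = text.index("</precursorList>") + len("</precursorList>")
        path.write_text(text[:start] + text[end:])
        with pytest.raises(FormatError, match="scan"):
            ps.read_mzml(path)

    def test_malformed_xml_rejected(self, tmp_path):
        path = tmp_path / "bad.mzml"
        path.write_text("<mzML><spectrum></mzML>")
        with pytest.raises(FormatError):
            ps.read_mzml(path)

    def test_second_unit_scan_times_converted_to_minutes(self, tmp_path):
        run = ps.LcmsRun("u", spectra=(ps.MassSpectrum(1, 2.0, ((100.0, 1.0),)),))
        path = tmp_path / "u.mzml"
        ps.write_mzml(run, path)
        text = path.read_text().replace('value="2.0" unitAccession="UO:0000031" unitName="minute"',
                                        'value="120.0" unitAccession="UO:0000010" unitName="second"')
        path.write_text(text)
        assert ps.read_mzml(path).spectra[0].retention_time == pytest.approx(2.0)


class TestFeatureCsv:
    def test_round_trip_preserves_all_fields(self, tmp_path):
        rng = np.random.default_rng(1)
        feats = random_features(rng, 10)
        path = tmp_path / "f.csv"
        ps.write_feature_csv(feats, path)
        assert ps.read_feature_csv(path) == feats

    def test_round_trip_preserves_ms2_spectra(self, tmp_path):
        ms2 = ps.MassSpectrum(2, 1.5, ((100.25, 7.0), (210.5, 3.0)),
                              precursor_mz=400.123)
        feats = [
            ps.ChromatographicFeature(mz=400.1, rt_apex=1.5, rt_start=1.4,
                                      rt_end=1.6, area=9.0, height=4.0, ms2=ms2),
            ps.ChromatographicFeature(mz=500.0, rt_apex=2.0, rt_start=1.9,
                                      rt_end=2.1, area=1.0, height=1.0),
        ]
        path = tmp_path / "ms2.csv"
        ps.write_feature_csv(feats, path)
        assert ps.read_feature_csv(path) == feats

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "e.csv"
        ps.write_feature_csv([], path)
        assert path.read_text().strip() == "mz,rt_apex,rt_start,rt_end,area,height"
        assert ps.read_feature_csv(path) == []

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("mz,rt_apex,rt_start,rt_end,area\n100,1,0.9,1.1,5\n")
        with pytest.raises(FormatError, match="height"):
            ps.read_feature_csv(path)

    def test_negative_area_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("mz,rt_apex,rt_start,rt_end,area,height\n100,1,0.9,1.1,-5,2\n")
        with pytest.raises(InvariantError):
            ps.read_feature_csv(path)
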