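"""Mass binning, thresholds, spectrum attachment, SNOG filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snoglyc.msms_profiling import score_spectra
from snoglyc.precursor_aggregation import (
    attach_spectra,
    bin_features,
    grid_center,
    read_histogram_tsv,
    snog_filter,
    threshold,
    tic_normalize,
)
from snoglyc.spectra_io import PrecursorFeature, RunConfig


def feat(mass, intensity=1e7, rt=1000.0):
    return PrecursorFeature(mass=mass, rt=rt, intensity=intensity, sample="t")


class TestBinFeatures:
    def test_single_feature_nearest_center(self, cfg):
        hist = bin_features([feat(2371.8638)], cfg, sample="t")
        assert len(hist) == 1
        assert hist.bins[0].center == pytest.approx(2371.9)
        assert hist.bins[0].intensity == 1e7

    def test_additivity_within_bin(self, cfg):
        hist = bin_features([feat(2000.01, 4e6), feat(2000.02, 3e6)], cfg, "t")
        assert len(hist) == 1
        assert hist.bins[0].intensity == pytest.approx(7e6)

    def test_out_of_range_dropped(self, cfg):
        hist = bin_features([feat(999.9)], cfg, "t")
        assert len(hist) == 0

    def test_order_independence(self, cfg):
        feats = [feat(1000.0 + i * 0.37, 1e6 * (i + 1)) for i in range(50)]
        h1 = bin_features(feats, cfg, "t")
        h2 = bin_features(list(reversed(feats)), cfg, "t")
        assert [(b.center, b.intensity) for b in h1.bins] == \
               [(b.center, b.intensity) for b in h2.bins]

    @given(st.lists(st.tuples(st.floats(900.0, 5100.0),
                              st.floats(1.0, 1e8)), max_size=60))
    def test_conservation_of_in_range_intensity(self, pairs):
        """Binned TIC equals the brute-force sum of in-range intensities."""
        cfg = RunConfig()
        feats = [feat(m, i) for m, i in pairs]
        hist = bin_features(feats, cfg, "t")
        expected = sum(
            i for m, i in pairs
            if cfg.bin_low - 1e-9 <= grid_center(m, cfg) <= cfg.bin_high + 1e-9
        )
        assert hist.tic == pytest.approx(expected, rel=1e-12, abs=1e-9)


class TestThreshold:
    def test_strictly_below_removed(self, cfg):
        hist = bin_features([feat(2000.0, 4.9e6), feat(3000.0, 5.1e6)], cfg, "t")
        out = threshold(hist)
        assert [b.intensity for b in out.bins] == [5.1e6]

    def test_all_below_warns(self, cfg):
        hist = bin_features([feat(2000.0, 1.0)], cfg, "t")
        with pytest.warns(UserWarning):
            out = threshold(hist)
        assert len(out) == 0

    def test_zero_threshold_is_identity(self, cfg):
        hist = bin_features([feat(2000.0, 1.0)], cfg, "t")
        assert len(threshold(hist, 0.0)) == 1


class TestAttachSpectra:
    def test_charge_deconvolution(self, cfg, spectrum_factory, registry):
        hist = bin_features([feat(2371.8638)], cfg, "t")
        s = spectrum_factory([(224.11, 1.0)], sid="q",
                             precursor_mz=1186.4355, charge=2)
        scores = score_spectra([s], registry)
        out = attach_spectra(hist, [s], scores)
        assert out.bins[0].spectra == ["q"]

    def test_nearest_center_tiebreak(self, cfg, spectrum_factory, registry):
        hist = bin_features([feat(2371.9), feat(2372.0)], cfg, "t")
        s = spectrum_factory([(224.11, 1.0)], sid="q",
                             precursor_mz=2371.97, charge=1)
        out = attach_spectra(hist, [s], score_spectra([s], registry))
        assert out.bin_at(2372.0).spectra == ["q"]
        assert out.bin_at(2371.9).spectra == []

    def test_z1_mass_equals_mz(self, cfg, spectrum_factory, registry):
        s = spectrum_factory([(224.11, 1.0)], precursor_mz=2000.0, charge=1)
        assert s.precursor_mass() == pytest.approx(2000.0)

    def test_unknown_charge_skipped(self, cfg, spectrum_factory, registry):
        hist = bin_features([feat(2000.0)], cfg, "t")
        s = spectrum_factory([(224.11, 1.0)], sid="q",
                             precursor_mz=2000.0, charge=None)
        out = attach_spectra(hist, [s], score_spectra([s], registry))
        assert out.bins[0].spectra == []


class TestSnogFilter:
    def test_weighted_mean_retention(self, cfg, spectrum_factory, registry):
        hist = bin_features([feat(2000.0)], cfg, "t")
        s1 = spectrum_factory([(224.11, 20.0), (500.0, 80.0)], sid="a",
                              precursor_mz=2000.0, charge=1)  # snog 0.2
        s2 = spectrum_factory([(224.11, 40.0), (500.0, 60.0)], sid="b",
                              precursor_mz=2000.0, charge=1)  # snog 0.4
        scores = score_spectra([s1, s2], registry)
        hist = attach_spectra(hist, [s1, s2], scores)
        out = snog_filter(hist, scores)
        assert len(out) == 1
        assert out.bins[0].snog == pytest.approx(0.3)

    def test_contaminant_bin_rejected(self, cfg, spectrum_factory, registry):
        hist = bin_features([feat(2000.0)], cfg, "t")
        s = spectrum_factory([(163.0601, 50.0), (325.1129, 50.0)], sid="c",
                             precursor_mz=2000.0, charge=1)  # snog 0
        scores = score_spectra([s], registry)
        hist = attach_spectra(hist, [s], scores)
        assert len(snog_filter(hist, scores)) == 0

    def test_no_evidence_bin_rejected(self, cfg, registry):
        hist = bin_features([feat(2000.0)], cfg, "t")
        assert len(snog_filter(hist, {})) == 0

    def test_precursor_intensity_weights(self, cfg, spectrum_factory, registry):
        hist = bin_features([feat(2000.0)], cfg, "t")
        s1 = spectrum_factory([(224.11, 20.0), (500.0, 80.0)], sid="a",
                              precursor_mz=2000.0, charge=1,
                              precursor_intensity=3.0)
        s2 = spectrum_factory([(224.11, 40.0), (500.0, 60.0)], sid="b",
                              precursor_mz=2000.0, charge=1,
                              precursor_intensity=1.0)
        scores = score_spectra([s1, s2], registry)
        hist = attach_spectra(hist, [s1, s2], scores)
        out = snog_filter(hist, scores, spectra=[s1, s2])
        assert out.bins[0].snog == pytest.approx((0.2 * 3 + 0.4 * 1) / 4)


class TestTicNormalize:
    def test_fractions(self, cfg):
        hist = bin_features([feat(2000.0, 6e6), feat(3000.0, 1.4e7)], cfg, "t")
        out = tic_normalize(hist)
        assert [b.intensity for b in out.bins] == pytest.approx([0.3, 0.7])
        assert out.tic == pytest.approx(1.0)

    def test_idempotent(self, cfg):
        hist = bin_features([feat(2000.0, 6e6), feat(3000.0, 1.4e7)], cfg, "t")
        once = tic_normalize(hist)
        twice = tic_normalize(once)
        assert [b.intensity for b in twice.bins] == \
            pytest.approx([b.intensity for b in once.bins])

    def test_zero_tic_errors(self, cfg):
        hist = bin_features([], cfg, "t")
        with pytest.raises(ValueError):
            tic_normalize(hist)


def test_histogram_tsv_roundtrip(cfg, tmp_path):
    hist = bin_features([feat(2371.8638, 1e7), feat(1237.4563, 5e6)], cfg, "t")
    p = tmp_path / "hist.tsv"
    hist.write_tsv(p)
    again = read_histogram_tsv(p, sample="t")
    assert [(b.center, b.intensity) for b in again.bins] == \
        pytest.approx([(b.center, b.intensity) for b in hist.bins])
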