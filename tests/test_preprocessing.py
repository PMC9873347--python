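"""Normalization, subband filtering, windowing, curation and splitting."""

import numpy as np
import pytest
from scipy import signal as sps

import ehgkit as ek
from ehgkit.io import WFDBError, read_wfdb_record, write_wfdb_record
from ehgkit.preprocessing import (DegenerateSignalError, design_bandpass,
                                  zscore)
from ehgkit.records import DEFAULT_BANDS, EHGRecord, band_by_name

FS = 20.0


def _record(label="P", ga=30.0, n=4800, seed=0, record_id="r0"):
    rng = np.random.default_rng(seed)
    return EHGRecord(
        record_id=record_id,
        channels={c: rng.standard_normal(n) for c in ("S1", "S2", "S3")},
        fs_hz=FS, label=label, gestational_age_rec_weeks=ga)


# ---------------------------------------------------------------------- io

class TestWFDBIO:
    def test_round_trip_within_quantization(self, tmp_path):
        rec = _record()
        rec.gestational_age_del_weeks = 38.2
        write_wfdb_record(rec, tmp_path, gain=1000.0)
        back = read_wfdb_record(tmp_path / "r0.hea")
        for ch in ("S1", "S2", "S3"):
            np.testing.assert_allclose(back.channels[ch], rec.channels[ch],
                                       atol=0.5 / 1000)
        assert back.label == "P"
        assert back.gestational_age_rec_weeks == 30.0
        assert back.gestational_age_del_weeks == 38.2

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(WFDBError, match="not found"):
            read_wfdb_record(tmp_path / "nope.hea")

    def test_wrong_channel_count_errors(self, tmp_path):
        (tmp_path / "two.hea").write_text(
            "two 2 20 100\ntwo.dat 16 1000(0)/mV 16 0 0 0 0 S1\n"
            "two.dat 16 1000(0)/mV 16 0 0 0 0 S2\n")
        (tmp_path / "two.dat").write_bytes(bytes(400))
        with pytest.raises(WFDBError, match="channel"):
            read_wfdb_record(tmp_path / "two.hea")

    def test_gestation_comment_parsed_as_recording_age(self, tmp_path):
        rec = _record(ga=None, record_id="g")
        write_wfdb_record(rec, tmp_path)
        hea = tmp_path / "g.hea"
        hea.write_text(hea.read_text() + "# Gestation 30.4\n")
        assert read_wfdb_record(hea).gestational_age_rec_weeks == 30.4

    def test_physionet_style_rectime_takes_precedence(self, tmp_path):
        rec = _record(ga=None, record_id="g")
        write_wfdb_record(rec, tmp_path)
        hea = tmp_path / "g.hea"
        hea.write_text(hea.read_text()
                       + "# Gestation 38.1\n# Rectime 30.2\n")
        back = read_wfdb_record(hea)
        assert back.gestational_age_rec_weeks == 30.2


# ------------------------------------------------------------------ zscore

class TestZscore:
    def test_closed_form(self):
        np.testing.assert_allclose(zscore(np.array([1.0, 2.0, 3.0])),
                                   [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_population_moments(self, rng):
        z = zscore(rng.standard_normal(1000) * 3 + 5)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_constant_errors(self):
        with pytest.raises(DegenerateSignalError):
            zscore(np.full(10, 2.5))

    def test_idempotent(self, rng):
        x = rng.standard_normal(500)
        np.testing.assert_allclose(zscore(zscore(x)), zscore(x), atol=1e-10)


# ---------------------------------------------------------------- bandpass

class TestBandpass:
    def test_passband_and_octave_stopband_gains(self):
        """Zero-phase response: >= 0.99 at midband, <= 0.1 one octave out."""
        for band in DEFAULT_BANDS:
            sos = design_bandpass(band, FS)
            mid = (band.low_hz + band.high_hz) / 2
            probe = [mid, band.low_hz / 2, band.high_hz * 2]
            w, h = sps.sosfreqz(sos, worN=np.array(probe), fs=FS)
            gains = np.abs(h) ** 2  # forward-backward application
            assert gains[0] >= 0.99, band.name
            assert gains[1] <= 0.1, band.name
            assert gains[2] <= 0.1, band.name

    def test_inband_tone_preserved(self):
        t = np.arange(36000) / FS
        x = np.sin(2 * np.pi * 0.65 * t)
        y = ek.bandpass(x, band_by_name("F1"), FS)[200:-200]
        assert abs(np.sqrt(np.mean(y ** 2)) / np.sqrt(0.5) - 1) < 0.02

    def test_out_of_band_tone_suppressed(self):
        t = np.arange(36000) / FS
        x = np.sin(2 * np.pi * 2.5 * t)
        y = ek.bandpass(x, band_by_name("F1"), FS)[200:-200]
        assert np.sqrt(np.mean(y ** 2)) / np.sqrt(0.5) <= 0.1

    def test_zero_in_zero_out(self):
        y = ek.bandpass(np.zeros(4800), band_by_name("F2"), FS)
        np.testing.assert_array_equal(y, 0.0)

    def test_linearity(self, rng):
        x = rng.standard_normal(4800)
        band = band_by_name("F1")
        y1 = ek.bandpass(3.7 * x, band, FS)
        y2 = 3.7 * ek.bandpass(x, band, FS)
        np.testing.assert_allclose(y1, y2, rtol=1e-10)

    def test_band_edge_at_nyquist_rejected(self):
        band = ek.BandDefinition("bad", 5.0, 10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ek.bandpass(np.zeros(100), band, FS)


# ----------------------------------------------------------------- windows

class TestSegmentWindows:
    def test_standard_record_window_count(self):
        ws = ek.segment_windows(np.zeros(36000), FS)
        assert len(ws) == 29
        assert all(len(w) == 2400 for w in ws)

    def test_half_overlap_shares_1200_samples(self, rng):
        x = rng.standard_normal(6000)
        ws = ek.segment_windows(x, FS)
        np.testing.assert_array_equal(ws[0][1200:], ws[1][:1200])

    def test_exact_one_window(self):
        assert len(ek.segment_windows(np.zeros(2400), FS)) == 1

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            ek.segment_windows(np.zeros(2399), FS)


# ---------------------------------------------------------------- curation

class TestCuration:
    def test_ga_filter_inclusive_bounds(self):
        recs = [_record(ga=g, record_id=f"r{i}")
                for i, g in enumerate([26.9, 27.0, 33.0, 33.1])]
        kept = ek.filter_records_by_ga(recs, 27, 33)
        assert [r.gestational_age_rec_weeks for r in kept] == [27.0, 33.0]
        assert recs[0].excluded and recs[3].excluded

    def test_ga_filter_empty_and_identity(self):
        assert ek.filter_records_by_ga([], 27, 33) == []
        recs = [_record(ga=30, record_id=f"r{i}") for i in range(3)]
        assert len(ek.filter_records_by_ga(recs, 27, 33)) == 3

    def test_ga_filter_missing_metadata_flagged(self):
        rec = _record(ga=None)
        assert ek.filter_records_by_ga([rec], 27, 33) == []
        assert rec.exclusion_reason == "no-metadata"

    def test_balance_by_subsampling(self):
        recs = ([_record("P", record_id=f"p{i}") for i in range(5)]
                + [_record("T", record_id=f"t{i}") for i in range(20)])
        sel = ek.balance_by_subsampling(recs, 5, seed=1)
        labels = [r.label for r in sel]
        assert labels.count("P") == labels.count("T") == 5
        sel2 = ek.balance_by_subsampling(recs, 5, seed=1)
        assert [r.record_id for r in sel] == [r.record_id for r in sel2]

    def test_balance_insufficient_class_named(self):
        recs = ([_record("P", record_id=f"p{i}") for i in range(5)]
                + [_record("T", record_id=f"t{i}") for i in range(20)])
        with pytest.raises(ValueError, match="class P"):
            ek.balance_by_subsampling(recs, 6, seed=0)


# ------------------------------------------------------------------ splits

class TestSplitRecords:
    @staticmethod
    def _cohort(n_per_class):
        return ([_record("P", record_id=f"p{i}") for i in range(n_per_class)]
                + [_record("T", record_id=f"t{i}")
                   for i in range(n_per_class)])

    def test_rounding_rule_20_per_class(self):
        split = ek.split_records(self._cohort(20), seed=0)
        for label in ("p", "t"):
            ids = [f"{label}{i}" for i in range(20)]
            counts = {s: sum(split[i] == s for i in ids)
                      for s in ("train", "validation", "test")}
            assert counts == {"train": 14, "validation": 3, "test": 3}

    def test_partition_disjoint_exhaustive(self):
        recs = self._cohort(10)
        split = ek.split_records(recs, seed=3)
        all_ids = {r.record_id for r in recs}
        assigned = (set(split.ids("train")) | set(split.ids("validation"))
                    | set(split.ids("test")))
        assert assigned == all_ids
        assert not set(split.ids("test")) & (set(split.ids("train"))
                                             | set(split.ids("validation")))

    def test_deterministic_given_seed(self):
        recs = self._cohort(10)
        assert (ek.split_records(recs, seed=5).assignment
                == ek.split_records(recs, seed=5).assignment)

    def test_all_train_fractions(self):
        split = ek.split_records(self._cohort(5), fractions=(1.0, 0.0, 0.0))
        assert all(v == "train" for v in split.assignment.values())

    def test_tiny_class_degenerates_with_warning(self):
        recs = ([_record("P", record_id="p0")]
                + [_record("T", record_id=f"t{i}") for i in range(5)])
        with pytest.warns(UserWarning, match="class P"):
            split = ek.split_records(recs, seed=0)
        assert split.degenerate
        assert split["p0"] == "train"
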