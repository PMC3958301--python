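"""Synthetic EEG generator and the EDF / annotation round trips."""

import numpy as np
import pytest

from eegreduce import features as feat
from eegreduce.edf import EDFFormatError, read_edf, write_edf
from eegreduce.features import EpochLabel, nlacc, segment_and_label
from eegreduce.synthetic_eeg import (EEGRecord, GeneratorConfig, SeizureEvent,
                                     background_std, generate_record,
                                     read_annotations, read_summary,
                                     write_annotations)


def _nlacc_by_label(record, n=512):
    """Channel-averaged NLACC per epoch, split by epoch label."""
    seiz, non = [], []
    for ep in segment_and_label(record, n):
        if ep.label == EpochLabel.MIXED:
            continue
        value = np.mean([nlacc(ch) for ch in ep.samples])
        (seiz if ep.label == EpochLabel.SEIZURE else non).append(value)
    return np.array(seiz), np.array(non)


def _pooled_sd(a, b):
    return np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)


class TestGenerator:
    def test_seeded_determinism(self):
        cfg = GeneratorConfig(duration_s=60, n_events=1,
                              event_duration_bounds=(6, 20), seed=11)
        r1, r2 = generate_record(cfg), generate_record(cfg)
        assert np.array_equal(r1.data, r2.data)
        assert r1.events == r2.events

    def test_zero_gain_labels_are_indistinguishable(self):
        # with no seizure activity injected, seizure-labeled epochs are
        # statistically identical to background; enough epochs per group
        # that the 0.1-pooled-SD bound sits well above sampling noise
        cfg = GeneratorConfig(n_channels=8, duration_s=14000, n_events=6,
                              event_duration_bounds=(650, 750),
                              seizure_gain=0.0, seed=21)
        seiz, non = _nlacc_by_label(generate_record(cfg))
        assert len(seiz) >= 200 and len(non) >= 200
        diff = abs(seiz.mean() - non.mean()) / _pooled_sd(seiz, non)
        assert diff < 0.1

    def test_high_gain_separates_by_five_pooled_sd(self):
        cfg = GeneratorConfig(n_channels=8, duration_s=14000, n_events=6,
                              event_duration_bounds=(650, 750),
                              seizure_gain=10.0, seed=21)
        seiz, non = _nlacc_by_label(generate_record(cfg))
        assert len(seiz) >= 200 and len(non) >= 200
        diff = (seiz.mean() - non.mean()) / _pooled_sd(seiz, non)
        assert diff > 5.0

    def test_background_mean_is_stationary(self):
        # 10-minute seizure-free record: per-channel mean within 3 standard
        # errors of zero, SE from the AR spectrum at zero frequency
        cfg = GeneratorConfig(n_channels=23, duration_s=600, n_events=0,
                              seed=4)
        rec = generate_record(cfg)
        a1, a2 = cfg.ar_coeffs
        se_mean = cfg.noise_scale / abs(1 - a1 - a2) / np.sqrt(rec.n_samples)
        assert np.all(np.abs(rec.data.mean(axis=1)) < 3 * se_mean + 0.5)

    def test_amplitudes_fit_16_bit_range(self):
        cfg = GeneratorConfig(duration_s=300, n_events=2,
                              event_duration_bounds=(20, 60),
                              seizure_gain=10.0, seed=9)
        rec = generate_record(cfg)
        assert np.abs(rec.data).max() < 32768

    def test_integer_amplitudes(self, small_record):
        assert np.array_equal(small_record.data,
                              np.rint(small_record.data))

    def test_unfittable_events_rejected(self):
        cfg = GeneratorConfig(duration_s=100, n_events=3,
                              event_duration_bounds=(40, 40), seed=0)
        with pytest.raises(ValueError, match="fit"):
            generate_record(cfg)

    def test_overlapping_events_rejected_on_record(self):
        with pytest.raises(ValueError, match="overlap"):
            EEGRecord(data=np.zeros((1, 1280)), fs=128.0,
                      channel_names=["C1"],
                      events=[SeizureEvent(1, 6), SeizureEvent(4, 9)])


class TestEDFRoundTrip:
    def test_round_trip_within_one_quantization_step(self, small_record,
                                                     tmp_path):
        path = tmp_path / "rec.edf"
        write_edf(small_record, path)
        back = read_edf(path)
        assert back.fs == small_record.fs
        assert back.n_channels == 23
        assert back.channel_names == small_record.channel_names
        step = (small_record.data.max() - small_record.data.min()) / 65535
        assert np.abs(back.data - small_record.data).max() <= step

    def test_non_edf_file_rejected(self, tmp_path):
        path = tmp_path / "notedf.edf"
        path.write_bytes(b"this is not an EDF file at all" * 20)
        with pytest.raises(EDFFormatError):
            read_edf(path)

    def test_mne_reads_our_edf(self, small_record, tmp_path):
        mne = pytest.importorskip("mne")
        path = tmp_path / "rec.edf"
        write_edf(small_record, path)
        raw = mne.io.read_raw_edf(path, verbose="error")
        data_uv = raw.get_data() * 1e6
        assert data_uv.shape == small_record.data.shape
        assert np.abs(data_uv - small_record.data).max() < 1.1


class TestAnnotations:
    def test_event_round_trip(self, tmp_path):
        rec = EEGRecord(data=np.zeros((1, 128 * 200)), fs=128.0,
                        channel_names=["C1"], record_id="recA",
                        events=[SeizureEvent(120, 180)])
        path = tmp_path / "summary.txt"
        write_annotations(rec, path)
        assert read_annotations(path) == [SeizureEvent(120, 180)]

    def test_zero_events(self, tmp_path):
        rec = EEGRecord(data=np.zeros((1, 1280)), fs=128.0,
                        channel_names=["C1"], record_id="recB")
        path = tmp_path / "summary.txt"
        write_annotations(rec, path)
        assert "Number of Seizures in File: 0" in path.read_text()
        assert read_annotations(path) == []

    def test_out_of_order_events_returned_sorted(self, tmp_path):
        path = tmp_path / "summary.txt"
        path.write_text(
            "File Name: recC.edf\n"
            "Number of Seizures in File: 2\n"
            "Seizure 1 Start Time: 300 seconds\n"
            "Seizure 1 End Time: 360 seconds\n"
            "Seizure 2 Start Time: 100 seconds\n"
            "Seizure 2 End Time: 130 seconds\n")
        events = read_annotations(path)
        assert [e.onset_s for e in events] == [100, 300]

    def test_malformed_line_names_line(self, tmp_path):
        path = tmp_path / "summary.txt"
        path.write_text("File Name: recD.edf\n"
                        "Seizure 1 Start Time: soon\n")
        with pytest.raises(ValueError, match="line 2"):
            read_summary(path)

    def test_multi_record_summary(self, tmp_path):
        path = tmp_path / "summary.txt"
        path.write_text(
            "File Name: a.edf\nNumber of Seizures in File: 1\n"
            "Seizure 1 Start Time: 10 seconds\n"
            "Seizure 1 End Time: 20 seconds\n\n"
            "File Name: b.edf\nNumber of Seizures in File: 0\n")
        blocks = read_summary(path)
        assert set(blocks) == {"a", "b"}
        assert blocks["b"] == []
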