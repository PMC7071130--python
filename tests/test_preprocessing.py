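"""Preprocessing pipeline: standardization, denoising, QRS detection,
segmentation, and the whole-chain invariants."""

from __future__ import annotations

import numpy as np
import pytest

import mlanet as m
from mlanet.leads import LEAD_NAMES
from mlanet.preprocessing import PreprocessConfig, QrsAnnotations


def _record_from_lead(lead_signal, fs=1000.0):
    """Embed one signal into lead II of an otherwise copied 12-lead record."""
    sigs = np.tile(lead_signal, (12, 1))
    return m.EcgRecord(sigs, fs=fs)


class TestStandardize:
    def test_three_point_min_max(self):
        sigs = np.tile([0.0, 5.0, 10.0], (12, 1))
        out = m.standardize(m.EcgRecord(sigs)).signals
        np.testing.assert_allclose(out, np.tile([-1.0, 0.0, 1.0], (12, 1)))

    def test_idempotent_on_saturated_range(self):
        rng = np.random.default_rng(0)
        sigs = rng.uniform(-1, 1, (12, 500))
        sigs[:, 0], sigs[:, 1] = -1.0, 1.0  # attain both bounds
        out = m.standardize(m.EcgRecord(sigs)).signals
        np.testing.assert_allclose(out, sigs, atol=1e-12)

    def test_constant_lead_becomes_zero_with_warning(self):
        sigs = np.random.default_rng(0).uniform(-1, 1, (12, 100))
        sigs[4] = 3.3
        with pytest.warns(UserWarning, match="constant"):
            out = m.standardize(m.EcgRecord(sigs)).signals
        np.testing.assert_array_equal(out[4], 0.0)
        assert out[[i for i in range(12) if i != 4]].min() == -1.0


class TestDenoiseDetrend:
    def test_zero_signal_stays_zero(self):
        rec = m.EcgRecord(np.zeros((12, 4096)))
        out = m.denoise_and_detrend(rec).signals
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_ramp_mostly_removed(self, clean_record):
        rec = m.standardize(clean_record)
        n = rec.n_samples
        ramp = 0.5 * np.arange(n) / n
        noisy = m.EcgRecord(rec.signals + ramp, fs=rec.fs)
        out = m.denoise_and_detrend(noisy, clip=False).signals
        t = np.arange(n)
        for i in range(12):
            slope_in = np.polyfit(t, noisy.signals[i], 1)[0]
            slope_out = np.polyfit(t, out[i], 1)[0]
            assert abs(slope_out) < 0.1 * abs(slope_in)

    def test_white_noise_rmse_reduced(self, clean_record):
        rec = m.standardize(clean_record)
        rng = np.random.default_rng(1)
        clean = m.denoise_and_detrend(rec, clip=False).signals
        noisy_rec = m.EcgRecord(
            rec.signals + rng.normal(0, 0.05, rec.signals.shape), fs=rec.fs)
        den = m.denoise_and_detrend(noisy_rec, clip=False).signals
        rmse_in = np.sqrt(np.mean((noisy_rec.signals - clean) ** 2))
        rmse_out = np.sqrt(np.mean((den - clean) ** 2))
        assert rmse_out < rmse_in

    def test_record_shorter_than_level_rejected(self):
        rec = m.EcgRecord(np.zeros((12, 100)))
        cfg = PreprocessConfig(decomposition_level=9)
        with pytest.raises(ValueError, match="lower"):
            m.denoise_and_detrend(rec, cfg)


class TestDetectQrs:
    def test_ten_beats_found_within_10ms(self, clean_record, clean_patient):
        rec = m.denoise_and_detrend(m.standardize(clean_record))
        ann = m.detect_qrs(rec)
        truth = m.true_qrs_centers(clean_patient, 10)
        assert len(ann.peak_indices) == 10
        np.testing.assert_array_less(np.abs(ann.peak_indices - truth), 10 + 1)

    def test_flat_record_yields_no_peaks(self):
        ann = m.detect_qrs(m.EcgRecord(np.zeros((12, 4000))))
        assert len(ann.peak_indices) == 0

    def test_refractory_period_suppresses_close_second_beat(self):
        beat = m.make_beat(m.BeatTemplate(), 1000, 400)[:300]
        sig = np.zeros(3000)
        sig[1000:1300] += beat
        sig[1150:1450] += beat  # second QRS 150 ms after the first
        ann = m.detect_qrs(_record_from_lead(sig))
        assert len(ann.peak_indices) == 1

    def test_noisy_record_still_finds_all_beats(self, imi_profile):
        pat = m.PatientProfile("p", noise_sd=0.05, wander_amp=0.1,
                               heart_rate=80.0)
        rec = m.generate_record(pat, imi_profile, 8, seed=2)
        rec = m.denoise_and_detrend(m.standardize(rec))
        assert len(m.detect_qrs(rec).peak_indices) == 8


class TestSegmentBeats:
    def _annotated(self, peaks):
        return QrsAnnotations(np.asarray(peaks))

    def test_five_interior_peaks_give_three_beats(self):
        rec = m.EcgRecord(np.random.default_rng(0).uniform(-1, 1, (12, 6000)))
        peaks = [500, 1500, 2500, 3500, 4500]
        beats = m.segment_beats(rec, self._annotated(peaks))
        assert len(beats) == 3
        for b in beats:
            assert b.L.shape == (12, 651)

    def test_window_content_is_the_expected_slice(self):
        rec = m.EcgRecord(np.random.default_rng(1).uniform(-1, 1, (12, 4000)))
        beats = m.segment_beats(rec, self._annotated([600, 1500, 2600]))
        np.testing.assert_array_equal(beats[0].L,
                                      rec.signals[:, 1500 - 250:1500 + 401])

    def test_margin_violating_peak_skipped_before_first_last_removal(self):
        rec = m.EcgRecord(np.zeros((12, 6000)))
        # peak at 100 has no 250-sample pre-margin; it must not count as
        # the "first" beat that gets removed
        beats = m.segment_beats(rec, self._annotated([100, 1000, 2000, 3000]))
        assert len(beats) == 1  # eligible: 1000,2000,3000 -> drop first/last

    def test_two_peaks_give_empty_output(self):
        rec = m.EcgRecord(np.zeros((12, 6000)))
        assert m.segment_beats(rec, self._annotated([1000, 2000])) == []

    def test_labels_and_patient_ids_copied(self):
        rec = m.EcgRecord(np.zeros((12, 6000)), patient_id="p9", label="AMI")
        beats = m.segment_beats(rec, self._annotated([1000, 2000, 3000]))
        assert beats[0].label == "AMI" and beats[0].patient_id == "p9"


class TestFullPipeline:
    def test_beats_are_12x651_in_unit_range_count_rule(self, imi_profile):
        pat = m.PatientProfile("p", noise_sd=0.03, heart_rate=72.0)
        rec = m.generate_record(pat, imi_profile, 10, seed=4)
        beats = m.preprocess_record(rec)
        assert len(beats) == 10 - 2
        for b in beats:
            assert b.L.shape == (12, 651)
            assert b.L.min() >= -1.0 and b.L.max() <= 1.0

    def test_pipeline_is_deterministic(self, imi_profile):
        pat = m.PatientProfile("p", noise_sd=0.03)
        rec = m.generate_record(pat, imi_profile, 6, seed=9)
        a = m.preprocess_record(rec)
        b = m.preprocess_record(rec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.L, y.L)

    def test_preprocess_records_pools_and_labels(self):
        recs = m.generate_dataset(2, ["HC", "IMI"], 5, seed=0, noise_sd=0.02)
        ds = m.preprocess_records(recs)
        assert ds.class_names == ("HC", "IMI")
        assert len(ds) == 4 * 3  # (5 - 2) beats per record
        assert set(ds.labels) == {"HC", "IMI"}


class TestConfig:
    def test_window_must_sum_to_beat_length(self):
        with pytest.raises(ValueError):
            PreprocessConfig(pre_samples=250, post_samples=399)

    def test_annotations_must_increase(self):
        with pytest.raises(ValueError):
            QrsAnnotations(np.array([5, 5, 9]))
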