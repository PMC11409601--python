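"""Preprocessing contracts: balancing, filtering, spectrograms, padding,
R-peak detection, beat segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgaf.io import EcgRecord
from ecgaf.preprocess import (
    BeatSegment,
    SPEC_BINS,
    detect_r_peaks,
    fir_bandpass,
    log_spectrogram,
    oversample_to_balance,
    pad_or_crop,
    segment_beats,
    standardize,
)


def _labeled(n, label, rng):
    return [EcgRecord(f"{label}{i}", rng.normal(size=300), label=label)
            for i in range(n)]


class TestOversampling:
    def test_exact_balance(self, rng):
        records = (_labeled(10, "NSR", rng) + _labeled(4, "AFib", rng)
                   + _labeled(2, "Other", rng) + _labeled(1, "Noisy", rng))
        out = oversample_to_balance(records, rng)
        counts = {c: sum(r.label == c for r in out)
                  for c in ("NSR", "AFib", "Other", "Noisy")}
        assert counts == {"NSR": 10, "AFib": 10, "Other": 10, "Noisy": 10}
        assert out[: len(records)] == records  # originals as prefix

    def test_balanced_input_unchanged(self, rng):
        records = _labeled(3, "NSR", rng) + _labeled(3, "AFib", rng)
        assert oversample_to_balance(records, rng) == records

    def test_idempotent(self, rng):
        records = _labeled(5, "NSR", rng) + _labeled(2, "AFib", rng)
        once = oversample_to_balance(records, rng)
        assert oversample_to_balance(once, rng) == once

    def test_copies_come_from_minority_class(self, rng):
        records = _labeled(6, "NSR", rng) + _labeled(2, "AFib", rng)
        out = oversample_to_balance(records, rng)
        assert all(r.label == "AFib" for r in out[len(records):])

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError):
            oversample_to_balance([], rng)


class TestBandpass:
    fs = 300.0
    t = np.arange(6000) / 300.0

    def test_stopband_attenuates_mains_hum(self):
        x = np.sin(2 * np.pi * 60.0 * self.t)
        y = fir_bandpass(x, self.fs)
        assert np.sqrt((y**2).mean()) <= 0.05 * np.sqrt((x**2).mean())

    def test_passband_preserves_qrs_band(self):
        x = np.sin(2 * np.pi * 10.0 * self.t)
        y = fir_bandpass(x, self.fs)
        assert np.sqrt((y**2).mean()) >= 0.90 * np.sqrt((x**2).mean())

    def test_zero_in_zero_out_same_length(self):
        y = fir_bandpass(np.zeros(1000), self.fs)
        assert y.shape == (1000,) and np.allclose(y, 0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            fir_bandpass(np.ones(100), self.fs, 40.0, 0.5)
        with pytest.raises(ValueError):
            fir_bandpass(np.ones(100), self.fs, 0.5, 200.0)


class TestStandardize:
    def test_basic_moments(self):
        y = standardize(np.array([1.0, 2.0, 3.0]))
        assert abs(y.mean()) < 1e-9 and abs(y.std() - 1.0) < 1e-9

    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(standardize(np.full(10, 3.3)), np.zeros(10))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_and_idempotence(self, seed):
        x = np.random.default_rng(seed).normal(size=64)
        a = np.random.default_rng(seed + 1).uniform(0.1, 10.0)
        b = np.random.default_rng(seed + 2).uniform(-5.0, 5.0)
        np.testing.assert_allclose(standardize(a * x + b), standardize(x),
                                   atol=1e-9)
        np.testing.assert_allclose(standardize(standardize(x)), standardize(x),
                                   atol=1e-9)


class TestSpectrogram:
    def test_frame_count_examples(self):
        assert log_spectrogram(np.random.default_rng(0).normal(size=18000)
                               ).values.shape == (64, 561)
        assert log_spectrogram(np.zeros(64)).values.shape == (64, 1)

    def test_all_zero_input_gives_log_eps(self):
        sp = log_spectrogram(np.zeros(128))
        np.testing.assert_allclose(sp.values, np.log(1e-6))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            log_spectrogram(np.zeros(63))

    @given(st.integers(64, 20000))
    @settings(max_examples=60, deadline=None)
    def test_frame_count_formula(self, length):
        sp = log_spectrogram(np.ones(length))
        assert sp.values.shape == (SPEC_BINS, (length - 64) // 32 + 1)


class TestPadOrCrop:
    def test_right_padding(self):
        y = pad_or_crop(np.arange(10.0), 16)
        np.testing.assert_array_equal(y[:10], np.arange(10.0))
        np.testing.assert_array_equal(y[10:], np.zeros(6))

    def test_center_crop_keeps_middle(self):
        y = pad_or_crop(np.arange(20.0), 16)
        np.testing.assert_array_equal(y, np.arange(2.0, 18.0))

    def test_identity_on_exact_length(self):
        x = np.arange(7.0)
        np.testing.assert_array_equal(pad_or_crop(x, 7), x)


class TestRPeaks:
    def test_zero_signal_gives_no_peaks(self):
        assert detect_r_peaks(np.zeros(3000), 300.0).size == 0

    def test_clean_nsr_peak_count_and_accuracy(self, clean_nsr):
        rec, truth, spec = clean_nsr
        det = detect_r_peaks(rec.signal, rec.fs)
        assert 29 <= det.size <= 31
        truth_idx = np.round(truth * rec.fs).astype(int)
        tol = int(0.05 * rec.fs)
        for t in truth_idx:
            assert np.min(np.abs(det - t)) <= tol

    def test_indices_strictly_increasing(self, binary_records):
        records, _ = binary_records
        for rec in records[:6]:
            det = detect_r_peaks(rec.signal, rec.fs)
            assert np.all(np.diff(det) > 0)


class TestBeatSegmentation:
    def test_boundary_peak_padded_with_zeros(self):
        sig = np.ones(900)
        segs = segment_beats(sig, np.array([0]), 300.0)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.values.shape == (600,)
        np.testing.assert_array_equal(seg.values[:300], np.zeros(300))
        np.testing.assert_array_equal(seg.values[300:], np.ones(300))

    def test_mid_record_segment_equals_raw_slice(self, rng):
        sig = rng.normal(size=3000)
        segs = segment_beats(sig, np.array([1500]), 300.0)
        np.testing.assert_array_equal(segs[0].values, sig[1200:1800])
        assert segs[0].r_index == 1500

    def test_one_segment_per_peak(self, rng):
        sig = rng.normal(size=3000)
        peaks = np.array([100, 700, 1500, 2900])
        segs = segment_beats(sig, peaks, 300.0)
        assert len(segs) == 4
        assert [s.r_index for s in segs] == list(peaks)
        assert all(isinstance(s, BeatSegment) for s in segs)
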