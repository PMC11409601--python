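"""Preprocessing: class balancing, filtering, standardization, spectrograms,
padding, R-peak detection, and beat segmentation.

The pipeline mirrors the four conceptual steps applied before the networks:
augmentation (see :mod:`ecgaf.augment`), filtering/transformation,
standardization, and padding. R-peaks are found with a Hamilton-style
adaptive-threshold detector so that beats can be cut into fixed two-second
segments around each apex.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .io import EcgRecord

# Spectrogram dialect: 64-sample Hann window, hop 32, exactly 64 one-sided
# bins. A one-sided transform of length 126 has floor(126/2)+1 = 64 bins,
# so each 64-sample window is zero-padded to 126 before the FFT — the
# (64-window, 64-bin) pairing is not natively consistent otherwise.
SPEC_WIN = 64
SPEC_HOP = 32
SPEC_NFFT = 126
SPEC_BINS = SPEC_NFFT // 2 + 1
LOG_EPS = 1e-6

#: Conventional diagnostic ECG band (Hz) and FIR length at 300 Hz.
DEFAULT_BAND = (0.5, 40.0)
DEFAULT_NUMTAPS = 301

#: Fixed padded length: 60 s at 300 Hz, covering the longest CinC recordings.
TARGET_LEN = 18000


@dataclass
class Spectrogram:
    """Log-magnitude time-frequency matrix, 64 bins x frames."""

    values: np.ndarray
    win: int = SPEC_WIN
    hop: int = SPEC_HOP

    def __post_init__(self):
        if self.values.shape[0] != SPEC_BINS:
            raise ValueError(f"spectrogram must have {SPEC_BINS} rows")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class BeatSegment:
    """A 2*fs-sample window centered on one R-peak."""

    values: np.ndarray
    r_index: int


def oversample_to_balance(records: list[EcgRecord],
                          rng: np.random.Generator) -> list[EcgRecord]:
    """Copy minority-class recordings until every present class matches the
    majority count. The input order is preserved as a prefix; appended items
    are verbatim copies drawn uniformly with replacement.
    """
    if not records:
        raise ValueError("cannot oversample an empty record list")
    by_class: dict[str, list[EcgRecord]] = {}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.record_id} has no label")
        by_class.setdefault(rec.label, []).append(rec)
    target = max(len(v) for v in by_class.values())
    out = list(records)
    for cls, members in by_class.items():
        deficit = target - len(members)
        if deficit > 0:
            picks = rng.integers(0, len(members), size=deficit)
            out.extend(copy.deepcopy(members[i]) for i in picks)
    return out


def fir_bandpass(signal: np.ndarray, fs: float,
                 low_hz: float = DEFAULT_BAND[0],
                 high_hz: float = DEFAULT_BAND[1],
                 numtaps: int = DEFAULT_NUMTAPS) -> np.ndarray:
    """Linear-phase FIR bandpass, group-delay compensated (same-length output)."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError("need 0 < low_hz < high_hz < fs/2")
    taps = scipy.signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs)
    return scipy.signal.fftconvolve(np.asarray(signal, dtype=float), taps,
                                    mode="same")


def standardize(signal: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling; constant input maps to zeros."""
    signal = np.asarray(signal, dtype=float)
    sd = signal.std()
    if sd == 0:
        return np.zeros_like(signal)
    return (signal - signal.mean()) / sd


def log_spectrogram(signal: np.ndarray) -> Spectrogram:
    """Log-magnitude spectrogram: Hann window 64, hop 32, 64 one-sided bins.

    Frame count is floor((L - 64) / 32) + 1; no frame centering. Values are
    log(|STFT| + 1e-6).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < SPEC_WIN:
        raise ValueError(f"signal shorter than one window ({SPEC_WIN})")
    frames = np.lib.stride_tricks.sliding_window_view(signal, SPEC_WIN)[::SPEC_HOP]
    window = scipy.signal.get_window("hann", SPEC_WIN)
    mag = np.abs(np.fft.rfft(frames * window, n=SPEC_NFFT, axis=1))
    return Spectrogram(values=np.log(mag + LOG_EPS).T)


def pad_or_crop(signal: np.ndarray, target_len: int = TARGET_LEN) -> np.ndarray:
    """Right-zero-pad short signals; center-crop long ones."""
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n == target_len:
        return signal.copy()
    if n < target_len:
        return np.concatenate([signal, np.zeros(target_len - n)])
    start = (n - target_len) // 2
    return signal[start : start + target_len].copy()


def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Hamilton-style QRS detection.

    Bandpass (8-16 Hz) -> differentiate -> rectify -> 80 ms moving-average
    envelope -> adaptive threshold between running signal/noise peak
    estimates, with a 200 ms refractory period and RR-based search-back.
    Detections are refined to the local extremum of the wide-band signal.
    Returns strictly increasing sample indices; may be empty.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(signal, dtype=float)
    if x.size < int(0.5 * fs) or np.all(x == x[0]):
        return np.array([], dtype=int)

    nyq = fs / 2.0
    b, a = scipy.signal.butter(2, [min(8.0, 0.4 * nyq) / nyq,
                                   min(16.0, 0.8 * nyq) / nyq], btype="band")
    filt = scipy.signal.filtfilt(b, a, x)
    env = np.abs(np.diff(filt, prepend=filt[0]))
    ma = max(1, int(0.08 * fs))
    env = np.convolve(env, np.ones(ma) / ma, mode="same")

    refractory = int(0.2 * fs)
    # candidate local maxima of the envelope
    cand, _ = scipy.signal.find_peaks(env, distance=max(1, refractory // 2))
    if cand.size == 0:
        return np.array([], dtype=int)

    spk = float(np.percentile(env[cand], 90))
    npk = float(np.percentile(env[cand], 10))
    peaks: list[int] = []
    rr_avg = None

    def accept(idx: int):
        nonlocal spk, rr_avg
        peaks.append(idx)
        spk = 0.8 * spk + 0.2 * env[idx]
        if len(peaks) >= 2:
            rr = peaks[-1] - peaks[-2]
            rr_avg = rr if rr_avg is None else 0.8 * rr_avg + 0.2 * rr

    i = 0
    while i < cand.size:
        idx = cand[i]
        thr = npk + 0.3125 * (spk - npk)
        if env[idx] > thr and (not peaks or idx - peaks[-1] > refractory):
            accept(idx)
        else:
            npk = 0.8 * npk + 0.2 * env[idx]
            # search-back: if a long gap has elapsed, accept the best
            # sub-threshold candidate above half the threshold
            if peaks and rr_avg and idx - peaks[-1] > 1.5 * rr_avg:
                window = cand[(cand > peaks[-1] + refractory) & (cand <= idx)]
                if window.size:
                    best = window[np.argmax(env[window])]
                    if env[best] > 0.5 * thr:
                        accept(int(best))
        i += 1

    # refine each detection to the dominant wide-band extremum nearby
    half = int(0.11 * fs)
    wide = x - np.convolve(x, np.ones(int(fs) | 1) / (int(fs) | 1), mode="same")
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(wide[lo:hi]))))
    refined = sorted(set(refined))
    out = [refined[0]] if refined else []
    for r in refined[1:]:
        if r - out[-1] > refractory:
            out.append(r)
    return np.array(out, dtype=int)


def segment_beats(signal: np.ndarray, rpeaks: np.ndarray,
                  fs: float) -> list[BeatSegment]:
    """Cut one 2*fs-sample window per R-peak (one second either side),
    zero-padding where the window exceeds the record bounds."""
    signal = np.asarray(signal, dtype=float)
    w = int(fs)
    segs = []
    for p in np.asarray(rpeaks, dtype=int):
        seg = np.zeros(2 * w)
        lo, hi = p - w, p + w
        src_lo, src_hi = max(0, lo), min(signal.size, hi)
        seg[src_lo - lo : src_hi - lo] = signal[src_lo:src_hi]
        segs.append(BeatSegment(values=seg, r_index=int(p)))
    return segs
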