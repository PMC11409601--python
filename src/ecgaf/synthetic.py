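"""Synthetic single-lead ECG generator with the four-class CinC structure.

The generator encodes the physiology that separates the classes:

* **NSR** — regular RR intervals (low coefficient of variation) with P-waves;
* **AFib** — irregular RR intervals (lognormal jitter, high CV), absent
  P-waves, and a low-amplitude 4–9 Hz fibrillatory baseline oscillation;
* **Other** — bigeminy-like alternating short/long RR with P-waves, so it is
  rhythmically distinct from both NSR and AFib;
* **Noisy** — NSR morphology buried in Gaussian noise at or above the QRS
  amplitude.

Beats are rendered as sums of five Gaussian bumps (P, Q, R, S, T) centered
on the cumulative RR positions, in the spirit of dynamical ECG simulators.
Records are emitted in the exact on-disk dialect of :mod:`ecgaf.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import CLASSES, DEFAULT_FS, EcgRecord, LabelFile, write_predictions, write_record

# Gaussian beat template: wave -> (center offset s, amplitude mV, width s).
# Amplitudes are relative to a 1 mV R-peak; offsets are relative to the R apex.
WAVE_TEMPLATE = {
    "P": (-0.160, 0.15, 0.035),
    "Q": (-0.035, -0.10, 0.012),
    "R": (0.000, 1.00, 0.016),
    "S": (0.035, -0.14, 0.014),
    "T": (0.280, 0.30, 0.070),
}
#: Fibrillatory ("f-wave") oscillation amplitude for beats without P-waves.
FIBRILLATORY_AMP = 0.05
FIBRILLATORY_BAND_HZ = (4.0, 9.0)
#: Short/long alternation depth of the bigeminy-like "Other" rhythm.
BIGEMINY_DEPTH = 0.35
#: Time of the first R apex within a record.
FIRST_PEAK_S = 0.4


@dataclass(frozen=True)
class RhythmSpec:
    """Conditions for one synthetic rhythm."""

    cls: str
    duration_s: float = 30.0
    fs: float = DEFAULT_FS
    rr_mean_s: float = 0.8
    rr_cv: float = 0.03
    p_wave: bool = True
    noise_sigma: float = 0.05
    bigeminy: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.cls not in CLASSES:
            raise ValueError(f"cls must be one of {CLASSES}")
        if not 0 < self.rr_mean_s < self.duration_s:
            raise ValueError("need 0 < rr_mean_s < duration_s")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")
        n = self.duration_s * self.fs
        if n < 1 or abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer >= 1")


#: Per-class default rhythm conditions.
CLASS_SPECS: dict[str, RhythmSpec] = {
    "NSR": RhythmSpec(cls="NSR", rr_mean_s=0.8, rr_cv=0.03, p_wave=True,
                      noise_sigma=0.05),
    "AFib": RhythmSpec(cls="AFib", rr_mean_s=0.7, rr_cv=0.25, p_wave=False,
                       noise_sigma=0.05),
    "Other": RhythmSpec(cls="Other", rr_mean_s=0.8, rr_cv=0.05, p_wave=True,
                        noise_sigma=0.05, bigeminy=True),
    "Noisy": RhythmSpec(cls="Noisy", rr_mean_s=0.8, rr_cv=0.03, p_wave=True,
                        noise_sigma=1.2),
}

#: Per-record mean-heart-rate ranges (seconds per beat), sampled uniformly.
RR_MEAN_RANGES = {
    "NSR": (0.60, 1.00),
    "AFib": (0.50, 0.90),
    "Other": (0.65, 1.00),
    "Noisy": (0.60, 1.00),
}


def generate_rr_series(spec: RhythmSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw beat-to-beat intervals whose cumulative sum stays within the record.

    Intervals follow a lognormal law parameterized to hit ``rr_mean_s`` and
    ``rr_cv`` exactly in expectation; ``rr_cv = 0`` degenerates to constant
    intervals. The bigeminy flag alternately shortens/lengthens intervals
    while preserving the pairwise mean.
    """
    if spec.rr_mean_s >= spec.duration_s:
        raise ValueError("rr_mean_s must be smaller than duration_s")
    n_max = int(np.ceil(spec.duration_s / spec.rr_mean_s * 3)) + 10
    if spec.rr_cv == 0:
        rr = np.full(n_max, spec.rr_mean_s)
    else:
        sigma2 = np.log1p(spec.rr_cv**2)
        mu = np.log(spec.rr_mean_s) - sigma2 / 2.0
        rr = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_max)
    if spec.bigeminy:
        mod = np.where(np.arange(n_max) % 2 == 0, 1.0 - BIGEMINY_DEPTH,
                       1.0 + BIGEMINY_DEPTH)
        rr = rr * mod
    # keep beats whose apex lands inside the record
    apex = FIRST_PEAK_S + np.concatenate([[0.0], np.cumsum(rr)[:-1]])
    keep = apex + rr <= spec.duration_s
    rr = rr[: int(np.argmin(keep)) if not keep.all() else n_max]
    return rr


def r_peak_times(rr: np.ndarray) -> np.ndarray:
    """Ground-truth R apex times (s) implied by an RR series."""
    rr = np.asarray(rr, dtype=float)
    return FIRST_PEAK_S + np.concatenate([[0.0], np.cumsum(rr)[:-1]])


def synthesize_ecg(rr: np.ndarray, spec: RhythmSpec,
                   rng: np.random.Generator,
                   record_id: str = "synthetic") -> EcgRecord:
    """Render an RR series into a sampled ECG waveform.

    Each beat contributes P, Q, R, S and T Gaussian bumps at its apex time;
    with ``p_wave=False`` the P bump is replaced record-wide by a 4–9 Hz
    fibrillatory oscillation. Additive white Gaussian noise is scaled by
    ``noise_sigma`` relative to the 1 mV R amplitude.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size and np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    signal = np.zeros(n)
    for apex in r_peak_times(rr):
        for wave, (off, amp, width) in WAVE_TEMPLATE.items():
            if wave == "P" and not spec.p_wave:
                continue
            center = apex + off
            lo = max(0, int((center - 4 * width) * spec.fs))
            hi = min(n, int((center + 4 * width) * spec.fs) + 1)
            if lo < hi:
                signal[lo:hi] += amp * np.exp(
                    -((t[lo:hi] - center) ** 2) / (2 * width**2)
                )
    if not spec.p_wave:
        freq = rng.uniform(*FIBRILLATORY_BAND_HZ)
        phase = rng.uniform(0, 2 * np.pi)
        signal += FIBRILLATORY_AMP * np.sin(2 * np.pi * freq * t + phase)
    if spec.noise_sigma > 0:
        signal += rng.normal(0.0, spec.noise_sigma, size=n)
    return EcgRecord(record_id=record_id, signal=signal, fs=spec.fs, label=spec.cls)


def generate_record(cls: str, record_id: str, rng: np.random.Generator,
                    base: RhythmSpec | None = None,
                    **overrides) -> tuple[EcgRecord, np.ndarray]:
    """Generate one labeled record; returns (record, ground-truth peak times)."""
    spec = base if base is not None else CLASS_SPECS[cls]
    lo, hi = RR_MEAN_RANGES[cls]
    if "rr_mean_s" not in overrides and base is None:
        overrides = {**overrides, "rr_mean_s": rng.uniform(lo, hi)}
    if overrides:
        spec = replace(spec, **overrides)
    rr = generate_rr_series(spec, rng)
    rec = synthesize_ecg(rr, spec, rng, record_id=record_id)
    return rec, r_peak_times(rr)


def generate_records(n_per_class: dict[str, int] | int, seed: int = 0,
                     **overrides) -> tuple[list[EcgRecord], dict[str, np.ndarray]]:
    """Generate records in memory; deterministic for a fixed seed.

    Returns the record list (class-blocked, ids ``<class index><serial>``)
    and a map record_id -> ground-truth R-peak times.
    """
    if isinstance(n_per_class, int):
        n_per_class = {cls: n_per_class for cls in CLASSES}
    for cls, n in n_per_class.items():
        if cls not in CLASSES or n < 0:
            raise ValueError(f"bad class count {cls!r}: {n}")
    rng = np.random.default_rng(seed)
    records, truth = [], {}
    for ci, cls in enumerate(CLASSES):
        for k in range(n_per_class.get(cls, 0)):
            rid = f"S{ci}{k:04d}"
            rec, peaks = generate_record(cls, rid, rng, **overrides)
            records.append(rec)
            truth[rid] = peaks
    return records, truth


def generate_dataset(n_per_class: dict[str, int] | int, out_dir: str | Path,
                     seed: int = 0, **overrides) -> tuple[Path, LabelFile]:
    """Write a format-valid synthetic dataset + REFERENCE.csv to ``out_dir``."""
    out_dir = Path(out_dir)
    records, _ = generate_records(n_per_class, seed=seed, **overrides)
    for rec in records:
        write_record(rec, out_dir)
    entries = [(rec.record_id, rec.label) for rec in records]
    write_predictions(entries, out_dir / "REFERENCE.csv")
    return out_dir, LabelFile(entries)
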