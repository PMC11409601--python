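"""Reading and writing ECG records and label files in the CinC-2017 dialect.

A record is stored as a MATLAB-v4 ``.mat`` file holding one integer sample
vector (ADC units), with a sibling WFDB-style ``.hea`` header carrying the
sampling rate and ADC gain. Reference labels and predictions are two-column
headerless CSV files (``record_id,symbol``) with symbols N/A/O/~ for
normal sinus rhythm, atrial fibrillation, other rhythm, and noisy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io

#: Class names in canonical index order 0..3; serialized symbols in the same order.
CLASSES = ("NSR", "AFib", "Other", "Noisy")
SYMBOLS = ("N", "A", "O", "~")
SYMBOL_TO_CLASS = dict(zip(SYMBOLS, CLASSES))
CLASS_TO_SYMBOL = dict(zip(CLASSES, SYMBOLS))

DEFAULT_FS = 300.0
DEFAULT_GAIN = 1000.0


@dataclass
class EcgRecord:
    """One single-lead ECG recording in physical units (millivolts)."""

    record_id: str
    signal: np.ndarray
    fs: float = DEFAULT_FS
    label: str | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValueError("signal must be a non-empty 1-D vector")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs

    def __eq__(self, other):
        if not isinstance(other, EcgRecord):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.fs == other.fs
            and self.label == other.label
            and np.array_equal(self.signal, other.signal)
        )


@dataclass
class LabelFile:
    """Ordered (record_id, class) pairs with unique record ids."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        ids = [rid for rid, _ in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({r for r in ids if ids.count(r) > 1})
            raise ValueError(f"duplicate record ids in label file: {dupes}")
        for rid, cls in self.entries:
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r} for record {rid!r}")

    def as_dict(self) -> dict[str, str]:
        return dict(self.entries)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _parse_header(path: Path) -> tuple[float, float]:
    """Return (fs, gain) from a WFDB .hea file; lenient about extra fields."""
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty header file: {path}")
    head = lines[0].split()
    fs = float(head[2]) if len(head) > 2 else DEFAULT_FS
    gain = DEFAULT_GAIN
    if len(lines) > 1:
        sig = lines[1].split()
        if len(sig) > 2:
            gain = float(sig[2].split("/")[0].split("(")[0])
    if fs <= 0 or gain <= 0:
        raise ValueError(f"non-positive fs/gain in header {path}")
    return fs, gain


def read_record(path: str | Path) -> EcgRecord:
    """Read a ``.mat``/``.hea`` pair, returning samples in physical units.

    The header, when present next to the ``.mat`` file, supplies the
    sampling rate and ADC gain; without one, the CinC-2017 conventions
    (300 Hz, gain 1000 per mV) apply. The record id is the filename stem.
    """
    path = Path(path)
    if path.suffix != ".mat":
        path = path.with_suffix(".mat")
    if not path.exists():
        raise FileNotFoundError(path)
    mat = scipy.io.loadmat(str(path))
    arrays = [v for k, v in mat.items() if not k.startswith("__")]
    if not arrays:
        raise ValueError(f"no sample vector found in {path}")
    raw = np.asarray(arrays[0]).ravel()
    if raw.size == 0:
        raise ValueError(f"empty signal in {path}")
    hea = path.with_suffix(".hea")
    fs, gain = _parse_header(hea) if hea.exists() else (DEFAULT_FS, DEFAULT_GAIN)
    return EcgRecord(record_id=path.stem, signal=raw.astype(np.float64) / gain, fs=fs)


def write_record(record: EcgRecord, out_dir: str | Path,
                 gain: float = DEFAULT_GAIN) -> tuple[Path, Path]:
    """Write ``<id>.mat`` + ``<id>.hea`` readable by :func:`read_record`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = np.round(record.signal * gain)
    if np.any(np.abs(raw) > np.iinfo(np.int16).max):
        raise ValueError("signal exceeds int16 range at this gain")
    mat_path = out_dir / f"{record.record_id}.mat"
    hea_path = out_dir / f"{record.record_id}.hea"
    scipy.io.savemat(str(mat_path), {"val": raw.astype(np.int16)[None, :]}, format="4")
    fs = int(record.fs) if float(record.fs).is_integer() else record.fs
    hea_path.write_text(
        f"{record.record_id} 1 {fs} {len(record.signal)}\n"
        f"{record.record_id}.mat 16 {gain:g}/mV 16 0 0 0 0 ECG\n"
    )
    return mat_path, hea_path


def _read_pairs(path: Path) -> list[tuple[str, str]]:
    pairs, bad = [], []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                bad.append((i, row))
                continue
            rid, sym = row[0].strip(), row[1].strip()
            if sym not in SYMBOL_TO_CLASS:
                bad.append((i, row))
                continue
            pairs.append((rid, SYMBOL_TO_CLASS[sym]))
    if bad:
        detail = "; ".join(f"line {i}: {row}" for i, row in bad)
        raise ValueError(f"invalid label rows in {path}: {detail}")
    return pairs


def read_labels(path: str | Path) -> LabelFile:
    """Parse a two-column headerless CSV of (record_id, N/A/O/~) rows."""
    return LabelFile(_read_pairs(Path(path)))


def write_predictions(entries: list[tuple[str, str]], path: str | Path) -> Path:
    """Write (record_id, class) pairs as the two-column answers CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for rid, cls in entries:
            if cls not in CLASS_TO_SYMBOL:
                raise ValueError(f"unknown class {cls!r} for record {rid!r}")
            fh.write(f"{rid},{CLASS_TO_SYMBOL[cls]}\n")
    return path


def load_dataset(records_dir: str | Path,
                 labels: str | Path | None = None) -> list[EcgRecord]:
    """Read every ``.mat`` record in a directory, attaching labels if given.

    Looks for ``REFERENCE.csv`` in the directory when ``labels`` is omitted.
    Records without a reference entry keep ``label=None`` — the
    score-as-NSR default is a scoring-time rule, not a storage rule.
    """
    records_dir = Path(records_dir)
    if labels is None:
        candidate = records_dir / "REFERENCE.csv"
        labels = candidate if candidate.exists() else None
    label_map = read_labels(labels).as_dict() if labels is not None else {}
    records = []
    for mat in sorted(records_dir.glob("*.mat")):
        rec = read_record(mat)
        rec.label = label_map.get(rec.record_id)
        records.append(rec)
    return records
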