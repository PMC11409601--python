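"""Challenge scoring: binary F1, macro F1, CinC F1, and a submission store.

Scoring conventions:

* every record in the reference without a prediction is scored as if it
  had been predicted ``NSR``;
* the binary F1 uses AFib as the positive class, keeps only records whose
  ground truth is NSR or AFib, and relabels predicted Other/Noisy as NSR;
* the macro F1 is the unweighted mean of the four one-vs-rest F1 terms;
* the CinC F1 averages the NSR, AFib and Other terms only (the official
  2017 challenge score).

Degenerate per-class 0/0 terms (class absent from both truth and
prediction) count as 1.0; a class present on exactly one side always has a
positive denominator and scores accordingly.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import CLASSES, read_labels

SUBMISSION_QUOTA = 5


@dataclass
class ConfusionMatrix:
    """Count table, rows = ground truth, columns = prediction."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative CxC table")

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]],
                   classes: tuple[str, ...] = CLASSES) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for truth, pred in pairs:
            counts[idx[truth], idx[pred]] += 1
        return cls(counts, classes)

    def tp_fp_fn(self, class_index: int) -> tuple[int, int, int]:
        tp = int(self.counts[class_index, class_index])
        fp = int(self.counts[:, class_index].sum() - tp)
        fn = int(self.counts[class_index, :].sum() - tp)
        return tp, fp, fn

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _f1_term(tp: int, fp: int, fn: int) -> float:
    denom = tp + 0.5 * (fp + fn)
    if denom == 0:
        return 1.0  # class absent from both truth and prediction
    return tp / denom


def _align(pred_entries, ref_entries) -> list[tuple[str, str]]:
    """(truth, pred) per reference record; missing predictions become NSR."""
    ref = list(ref_entries)
    pred = dict(pred_entries)
    extra = set(pred) - {rid for rid, _ in ref}
    if extra:
        raise ValueError(f"predictions for unknown record ids: {sorted(extra)}")
    return [(cls, pred.get(rid, "NSR")) for rid, cls in ref]


def relabel_for_binary(pred_entries, ref_entries) -> list[tuple[str, str]]:
    """Apply the binary-scoring conventions; returns (truth, pred) pairs.

    Records whose ground truth is Other/Noisy are dropped; predicted
    Other/Noisy (and missing predictions) count as NSR.
    """
    pairs = _align(pred_entries, ref_entries)
    out = []
    for truth, pred in pairs:
        if truth not in ("NSR", "AFib"):
            continue
        out.append((truth, pred if pred in ("NSR", "AFib") else "NSR"))
    return out


def f1_binary(pairs: list[tuple[str, str]]) -> float:
    """F1 with AFib positive on relabeled (truth, pred) pairs."""
    tp = sum(1 for t, p in pairs if t == "AFib" and p == "AFib")
    fp = sum(1 for t, p in pairs if t != "AFib" and p == "AFib")
    fn = sum(1 for t, p in pairs if t == "AFib" and p != "AFib")
    return _f1_term(tp, fp, fn)


def f1_macro(pred_entries, ref_entries) -> float:
    """Unweighted mean of the four one-vs-rest F1 terms."""
    cm = ConfusionMatrix.from_pairs(_align(pred_entries, ref_entries))
    return float(np.mean([_f1_term(*cm.tp_fp_fn(i)) for i in range(4)]))


def f1_cinc(pred_entries, ref_entries) -> float:
    """Mean of the NSR, AFib and Other terms (official 2017 score);
    Noisy stays in the confusion matrix but not in the average."""
    cm = ConfusionMatrix.from_pairs(_align(pred_entries, ref_entries))
    return float(np.mean([_f1_term(*cm.tp_fp_fn(i)) for i in range(3)]))


@dataclass
class ScoreReport:
    f1_binary: float
    f1_macro: float
    f1_cinc: float
    per_class_f1: dict[str, float]
    accuracy: float
    confusion_binary: ConfusionMatrix
    confusion_multiclass: ConfusionMatrix
    auroc: float | None = None
    auprc: float | None = None
    n_records: int = 0

    def as_dict(self) -> dict:
        d = {
            "f1_binary": self.f1_binary,
            "f1_macro": self.f1_macro,
            "f1_cinc": self.f1_cinc,
            "per_class_f1": self.per_class_f1,
            "accuracy": self.accuracy,
            "n_records": self.n_records,
            "confusion_multiclass": self.confusion_multiclass.counts.tolist(),
            "confusion_binary": self.confusion_binary.counts.tolist(),
        }
        if self.auroc is not None:
            d["auroc"] = self.auroc
        if self.auprc is not None:
            d["auprc"] = self.auprc
        return d


def score_entries(pred_entries, ref_entries,
                  probs: dict[str, np.ndarray] | None = None) -> ScoreReport:
    """Full score report from in-memory label (and optional probability) maps."""
    pairs4 = _align(pred_entries, ref_entries)
    cm4 = ConfusionMatrix.from_pairs(pairs4)
    per_class = {c: _f1_term(*cm4.tp_fp_fn(i)) for i, c in enumerate(CLASSES)}
    pairs2 = relabel_for_binary(pred_entries, ref_entries)
    cm2 = ConfusionMatrix.from_pairs(pairs2, classes=("NSR", "AFib"))
    accuracy = float(np.trace(cm4.counts) / cm4.total) if cm4.total else 0.0
    auroc = auprc = None
    if probs:
        auroc, auprc = _prob_scores(probs, ref_entries)
    return ScoreReport(
        f1_binary=f1_binary(pairs2),
        f1_macro=float(np.mean(list(per_class.values()))),
        f1_cinc=float(np.mean([per_class[c] for c in ("NSR", "AFib", "Other")])),
        per_class_f1=per_class,
        accuracy=accuracy,
        confusion_binary=cm2,
        confusion_multiclass=cm4,
        auroc=auroc,
        auprc=auprc,
        n_records=cm4.total,
    )


def _prob_scores(probs: dict[str, np.ndarray], ref_entries):
    """Macro one-vs-rest AUROC/AUPRC over the classes present in the truth."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    rows = [(cls, probs[rid]) for rid, cls in ref_entries if rid in probs]
    if not rows:
        return None, None
    y = np.array([CLASSES.index(cls) for cls, _ in rows])
    p = np.vstack([np.asarray(row, dtype=float) for _, row in rows])
    n_classes = p.shape[1]
    aurocs, auprcs = [], []
    for i in range(n_classes):
        pos = (y == i).astype(int)
        if pos.min() == pos.max():
            continue  # class absent (or universal): score undefined
        aurocs.append(roc_auc_score(pos, p[:, i]))
        auprcs.append(average_precision_score(pos, p[:, i]))
    if not aurocs:
        return None, None
    return float(np.mean(aurocs)), float(np.mean(auprcs))


def _read_probs(path: str | Path) -> dict[str, np.ndarray]:
    out = {}
    for line in Path(path).read_text().splitlines():
        parts = [p.strip() for p in line.split(",") if p.strip()]
        if len(parts) < 2:
            continue
        out[parts[0]] = np.array([float(v) for v in parts[1:]])
    return out


def score_submission(pred_file: str | Path, ref_file: str | Path,
                     probs_file: str | Path | None = None) -> ScoreReport:
    """Score a two-column answers CSV against a REFERENCE.csv."""
    pred = list(read_labels(pred_file))
    ref = list(read_labels(ref_file))
    probs = _read_probs(probs_file) if probs_file else None
    return score_entries(pred, ref, probs)


# -- local submission store ----------------------------------------------------


class QuotaExceededError(RuntimeError):
    pass


_SCHEMA = """
CREATE TABLE IF NOT EXISTS teams (
    name TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS runs (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    team TEXT NOT NULL REFERENCES teams(name),
    model_name TEXT NOT NULL,
    created REAL NOT NULL,
    success INTEGER NOT NULL DEFAULT 1,
    f1_binary REAL, f1_macro REAL, f1_cinc REAL, accuracy REAL,
    report_json TEXT,
    log_digest TEXT,
    metadata_json TEXT
);
"""


class SubmissionStore:
    """Single-file relational store for scored submissions + ranking table."""

    def __init__(self, path: str | Path = "runs.sqlite"):
        self.conn = sqlite3.connect(str(path))
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self):
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def successful_runs(self, team: str) -> int:
        cur = self.conn.execute(
            "SELECT COUNT(*) FROM runs WHERE team = ? AND success = 1", (team,))
        return int(cur.fetchone()[0])

    def record_run(self, team: str, model_name: str, report: ScoreReport,
                   metadata: dict | None = None, console_log: str = "",
                   override_quota: bool = False) -> list[dict]:
        """Persist one scored run and return the refreshed ranking.

        Each team is allowed SUBMISSION_QUOTA successful runs; further ones
        are rejected unless ``override_quota`` is set.
        """
        if not override_quota and self.successful_runs(team) >= SUBMISSION_QUOTA:
            raise QuotaExceededError(
                f"team {team!r} already has {SUBMISSION_QUOTA} successful runs")
        self.conn.execute("INSERT OR IGNORE INTO teams (name) VALUES (?)", (team,))
        digest = hashlib.sha256(console_log.encode()).hexdigest()[:16]
        self.conn.execute(
            "INSERT INTO runs (team, model_name, created, success, f1_binary,"
            " f1_macro, f1_cinc, accuracy, report_json, log_digest,"
            " metadata_json) VALUES (?,?,?,?,?,?,?,?,?,?,?)",
            (team, model_name, time.time(), 1, report.f1_binary,
             report.f1_macro, report.f1_cinc, report.accuracy,
             json.dumps(report.as_dict()), digest,
             json.dumps(metadata or {})),
        )
        self.conn.commit()
        return self.ranking()

    def ranking(self, by: str = "f1_binary") -> list[dict]:
        """Best run per team, sorted by the configured score (descending)."""
        if by not in ("f1_binary", "f1_macro", "f1_cinc", "accuracy"):
            raise ValueError(f"unknown ranking score {by!r}")
        cur = self.conn.execute(
            f"SELECT team, model_name, MAX({by}) AS score FROM runs "
            f"WHERE success = 1 GROUP BY team ORDER BY score DESC"
        )
        return [
            {"position": i + 1, "team": team, "model_name": model, "score": score}
            for i, (team, model, score) in enumerate(cur.fetchall())
        ]
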