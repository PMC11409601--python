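"""Scoring rules: relabeling conventions, the three F1 scores, oracle
equivalence, and the submission store."""

import numpy as np
import pytest

from ecgaf.evaluate import (
    ConfusionMatrix,
    QuotaExceededError,
    SubmissionStore,
    f1_binary,
    f1_cinc,
    f1_macro,
    relabel_for_binary,
    score_entries,
    score_submission,
)
from ecgaf.io import CLASSES, write_predictions

REFS = [("r1", "NSR"), ("r2", "AFib"), ("r3", "Other"), ("r4", "Noisy")]


class TestRelabeling:
    def test_other_and_noisy_truths_dropped_predictions_mapped(self):
        preds = [("r1", "NSR"), ("r2", "AFib"), ("r3", "NSR"), ("r4", "NSR")]
        pairs = relabel_for_binary(preds, REFS)
        assert pairs == [("NSR", "NSR"), ("AFib", "AFib")]

    def test_other_prediction_on_afib_truth_becomes_false_negative(self):
        pairs = relabel_for_binary([("r2", "Other")], REFS)
        assert ("AFib", "NSR") in pairs

    def test_missing_predictions_default_to_nsr(self):
        pairs = relabel_for_binary([], REFS)
        assert pairs == [("NSR", "NSR"), ("AFib", "NSR")]

    def test_unknown_prediction_id_rejected(self):
        with pytest.raises(ValueError):
            relabel_for_binary([("ghost", "NSR")], REFS)

    def test_idempotent_on_already_binary_inputs(self):
        preds = [("r1", "AFib"), ("r2", "NSR")]
        once = relabel_for_binary(preds, REFS[:2])
        assert once == [("NSR", "AFib"), ("AFib", "NSR")]

    def test_dropping_other_truth_record_never_changes_f1(self):
        preds = [("r1", "NSR"), ("r2", "AFib"), ("r3", "AFib")]
        with_other = f1_binary(relabel_for_binary(preds, REFS))
        without = f1_binary(relabel_for_binary(preds[:2], REFS[:2]))
        assert with_other == without


class TestBinaryF1:
    def test_hand_counts(self):
        pairs = ([("AFib", "AFib")] * 8 + [("NSR", "AFib")] * 2
                 + [("AFib", "NSR")] * 2)
        assert f1_binary(pairs) == pytest.approx(0.8)

    def test_perfect_predictions(self):
        assert f1_binary([("AFib", "AFib"), ("NSR", "NSR")]) == 1.0

    def test_all_nsr_predictor_scores_zero(self):
        assert f1_binary([("AFib", "NSR"), ("NSR", "NSR")]) == 0.0

    def test_degenerate_no_positives_anywhere(self):
        assert f1_binary([("NSR", "NSR")]) == 1.0


def _balanced_refs(n=10):
    return [(f"{c}{i}", c) for c in CLASSES for i in range(n)]


class TestMultiClassScores:
    def test_perfect_macro_and_cinc(self):
        refs = _balanced_refs()
        assert f1_macro(refs, refs) == 1.0
        assert f1_cinc(refs, refs) == 1.0

    def test_always_nsr_on_balanced_set(self):
        refs = _balanced_refs()
        preds = [(rid, "NSR") for rid, _ in refs]
        assert f1_macro(preds, refs) == pytest.approx(0.1)
        assert f1_cinc(preds, refs) == pytest.approx(0.4 / 3)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(0)
        refs = _balanced_refs(5)
        preds = [(rid, CLASSES[rng.integers(0, 4)]) for rid, _ in refs]
        shuffled = [preds[i] for i in rng.permutation(len(preds))]
        assert f1_macro(preds, refs) == f1_macro(shuffled, refs)

    def test_degenerate_absent_class_counts_as_one(self):
        refs = [("a", "NSR"), ("b", "AFib")]
        preds = [("a", "NSR"), ("b", "AFib")]
        # Other and Noisy absent from both truth and prediction -> 1.0 each
        assert f1_macro(preds, refs) == 1.0


def brute_force_counts(pairs, cls):
    tp = sum(1 for t, p in pairs if t == cls and p == cls)
    fp = sum(1 for t, p in pairs if t != cls and p == cls)
    fn = sum(1 for t, p in pairs if t == cls and p != cls)
    return tp, fp, fn


def test_confusion_matrix_matches_brute_force_counting():
    rng = np.random.default_rng(99)
    for _ in range(300):
        n = int(rng.integers(1, 100))
        pairs = [(CLASSES[rng.integers(0, 4)], CLASSES[rng.integers(0, 4)])
                 for _ in range(n)]
        cm = ConfusionMatrix.from_pairs(pairs)
        for i, cls in enumerate(CLASSES):
            assert cm.tp_fp_fn(i) == brute_force_counts(pairs, cls)


def test_macro_f1_agrees_with_sklearn_on_random_sets():
    from sklearn.metrics import f1_score

    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(1, 200))
        refs = [(f"r{i}", CLASSES[rng.integers(0, 4)]) for i in range(n)]
        preds = [(f"r{i}", CLASSES[rng.integers(0, 4)]) for i in range(n)]
        ours = f1_macro(preds, refs)
        theirs = f1_score([c for _, c in refs], [c for _, c in preds],
                          labels=list(CLASSES), average="macro",
                          zero_division=1.0)
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestScoreReport:
    def test_perfect_file_pair(self, tmp_path):
        refs = _balanced_refs(3)
        write_predictions(refs, tmp_path / "REFERENCE.csv")
        write_predictions(refs, tmp_path / "answers.csv")
        report = score_submission(tmp_path / "answers.csv",
                                  tmp_path / "REFERENCE.csv")
        assert report.f1_binary == report.f1_macro == report.f1_cinc == 1.0
        assert report.accuracy == 1.0 and report.n_records == 12

    def test_random_predictions_stay_in_unit_interval(self):
        rng = np.random.default_rng(1)
        refs = _balanced_refs(8)
        preds = [(rid, CLASSES[rng.integers(0, 4)]) for rid, _ in refs]
        probs = {rid: rng.dirichlet(np.ones(4)) for rid, _ in refs}
        report = score_entries(preds, refs, probs)
        for v in (report.f1_binary, report.f1_macro, report.f1_cinc,
                  report.accuracy, report.auroc, report.auprc,
                  *report.per_class_f1.values()):
            assert 0.0 <= v <= 1.0


class TestSubmissionStore:
    def _report(self, f1=0.5):
        refs = _balanced_refs(2)
        preds = [(rid, c) for rid, c in refs]
        report = score_entries(preds, refs)
        report.f1_binary = f1
        return report

    def test_ranking_sorted_by_score(self, tmp_path):
        with SubmissionStore(tmp_path / "runs.sqlite") as store:
            store.record_run("alpha", "m1", self._report(0.6))
            ranking = store.record_run("beta", "m2", self._report(0.9))
        assert [r["team"] for r in ranking] == ["beta", "alpha"]
        assert ranking[0]["position"] == 1

    def test_quota_of_five_enforced_with_override(self, tmp_path):
        with SubmissionStore(tmp_path / "runs.sqlite") as store:
            for _ in range(5):
                store.record_run("team", "m", self._report())
            with pytest.raises(QuotaExceededError):
                store.record_run("team", "m", self._report())
            store.record_run("team", "m", self._report(), override_quota=True)
            assert store.successful_runs("team") == 6

    def test_rescoring_identical_file_is_idempotent_in_ranking(self, tmp_path):
        with SubmissionStore(tmp_path / "runs.sqlite") as store:
            r1 = store.record_run("team", "m", self._report(0.7))
            r2 = store.record_run("team", "m", self._report(0.7))
        assert r1 == r2
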