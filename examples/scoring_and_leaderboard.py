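"""Score prediction files with the challenge metrics and keep a leaderboard.

Shows the three scores and their conventions: the binary F1 (AFib
positive, Other/Noisy predictions relabeled to NSR, non-binary truths
dropped), the four-class macro F1, and the CinC F1 (mean of the NSR, AFib
and Other terms). Runs are persisted in a single-file SQL store with a
five-submission quota per team.
"""

import numpy as np

from ecgaf.evaluate import SubmissionStore, score_entries
from ecgaf.io import CLASSES

rng = np.random.default_rng(0)
refs = [(f"rec{i:03d}", CLASSES[rng.integers(0, 4)]) for i in range(200)]

# a decent predictor: 85% correct, errors uniform over the other classes
preds = []
for rid, cls in refs:
    if rng.random() < 0.85:
        preds.append((rid, cls))
    else:
        others = [c for c in CLASSES if c != cls]
        preds.append((rid, others[rng.integers(0, 3)]))

report = score_entries(preds, refs)
print(f"binary F1 (AFib+): {report.f1_binary:.3f}")
print(f"macro F1 (4-way):  {report.f1_macro:.3f}")
print(f"CinC F1 (N/A/O):   {report.f1_cinc:.3f}")
print(f"accuracy:          {report.accuracy:.3f}")
print("confusion (rows = truth N/A/O/~):")
print(report.confusion_multiclass.counts)

with SubmissionStore("scratch_runs.sqlite") as store:
    ranking = store.record_run("demo-team", "noisy-oracle", report,
                               override_quota=True)
print("\nleaderboard (by binary F1):")
for row in ranking:
    print(f"  #{row['position']} {row['team']} ({row['model_name']}): "
          f"{row['score']:.3f}")

# All three scores live in [0, 1]; the macro F1 is dragged down relative
# to accuracy whenever a rare class is missed, which is the point of using
# it under class imbalance.
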