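"""Classify AFib vs NSR with the beat-interval baseline.

The baseline detects R-peaks, computes beat-to-beat intervals (BBIs), and
calls a record AFib when the standard deviation of its BBIs exceeds a
threshold (default 0.1 s) — exploiting that atrial fibrillation produces
irregular ventricular response intervals.
"""

import numpy as np

from ecgaf.evaluate import f1_binary
from ecgaf.models import baseline_bbi
from ecgaf.synthetic import generate_records

records, _ = generate_records({"NSR": 50, "AFib": 50}, seed=7)
pairs = [(rec.label, baseline_bbi(rec, threshold=0.1).label)
         for rec in records]
correct = sum(t == p for t, p in pairs)
print(f"records: {len(pairs)}, correct: {correct}")
print(f"binary F1 (AFib positive): {f1_binary(pairs):.3f}")

# With the generator's class conditions (NSR RR CV ~0.03, AFib ~0.25) the
# interval s.d. gap is wide, so the F1 should be close to 1.0 — this is the
# physiology the threshold rule exploits, not a property of the detector.
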