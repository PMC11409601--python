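"""Generate a synthetic four-class ECG dataset and inspect its rhythm statistics.

Writes CinC-2017-dialect records (.mat + .hea + REFERENCE.csv) and prints
the beat-to-beat interval statistics per class: NSR should show a low
coefficient of variation (regular rhythm), AFib a high one (irregular),
and the bigeminy-like "Other" class an alternating short/long pattern.
"""

import numpy as np

from ecgaf.io import load_dataset
from ecgaf.preprocess import detect_r_peaks
from ecgaf.synthetic import generate_dataset

out_dir, labels = generate_dataset(n_per_class=5, out_dir="scratch_dataset",
                                   seed=42)
print(f"wrote {len(labels)} records to {out_dir}/")

records = load_dataset(out_dir)
print(f"{'class':<8} {'records':>7} {'mean RR (s)':>12} {'RR CV':>7}")
for cls in ("NSR", "AFib", "Other", "Noisy"):
    cvs, means = [], []
    for rec in records:
        if rec.label != cls:
            continue
        peaks = detect_r_peaks(rec.signal, rec.fs)
        if peaks.size > 3:
            rr = np.diff(peaks) / rec.fs
            means.append(rr.mean())
            cvs.append(rr.std() / rr.mean())
    print(f"{cls:<8} {len(means):>7} {np.mean(means):>12.3f} {np.mean(cvs):>7.3f}")

# Expected pattern: NSR CV ~ 0.03 (regular), AFib CV > 0.2 (irregular),
# Other elevated by the alternating bigeminy intervals, Noisy unreliable
# because detection degrades under heavy noise.
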