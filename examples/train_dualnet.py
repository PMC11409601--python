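"""Train a small dual-domain network on synthetic NSR/AFib records.

The model encodes the raw signal with an LSTM into a latent vector and
the log-spectrogram with a conditional-batch-norm residual CNN; training
minimizes class-weighted cross-entropy with RAdam and a stepped learning
rate (x0.1 after 25/50/75% of the steps). Takes a couple of minutes on a
laptop CPU at this scale.
"""

import numpy as np

from ecgaf import nn
from ecgaf.augment import AugmentationConfig
from ecgaf.models import ModelConfig, build_model, predict_dataset
from ecgaf.synthetic import generate_records
from ecgaf.train import TrainConfig, fit

records, _ = generate_records({"NSR": 100, "AFib": 100}, seed=11,
                              duration_s=10.0)
order = np.random.default_rng(0).permutation(len(records))
train = [records[i] for i in order[:160]]
val = [records[i] for i in order[160:]]

nn.seed_init(1)
model = build_model(ModelConfig(family="dualnet", size="S", n_classes=2,
                                target_len=3000))
model, history = fit(model, train, val,
                     TrainConfig(epochs=8, batch_size=8, seed=1),
                     AugmentationConfig())

for h in history:
    print(f"epoch {h['epoch']:>2}: train loss {h['train_loss']:.3f}  "
          f"val F1 {h['val_f1']:.3f}")

preds = predict_dataset(model, val[:5])
print("\nsample predictions (best-validation checkpoint):")
for rec, pred in zip(val[:5], preds):
    print(f"  {rec.record_id}: truth {rec.label:<5} -> {pred.label:<5} "
          f"p = {np.round(pred.probs, 3)}")

# The loss should fall below the ln 2 ~ 0.69 chance level within a few
# epochs and the validation F1 should reach ~0.85-0.9 on this deliberately
# small 200-record run: the synthetic classes are separable by both rhythm
# (RR irregularity) and spectrum (fibrillatory 4-9 Hz band). Doubling the
# data and training for 10 epochs, as scripts/acceptance.py does, pushes
# the held-out F1 above 0.95.
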