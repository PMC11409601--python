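"""Weighted cross-entropy training with the staged recipe.

The loss is

    L = -(1/N) * sum_j sum_i alpha_i * y_ji * log(yhat_ji)

over a mini-batch of N softmax predictions, with per-class weights alpha
countering class imbalance (inverse-frequency, normalized to mean 1 — the
weighting scheme itself is a package choice). Optimization uses RAdam with
an initial rate of 1e-3, decayed by 0.1 after 25%, 50% and 75% of the
total steps; momentum factors (0.9, 0.999). Augmentation fires on-the-fly
with per-operator probability 0.2.

The staged recipe for the two-branch network pretrains the global ResNet
branch and the local beat CNN separately, then trains the full CLSTM, and
finally tunes only the fused classification head for a single epoch with
both branches frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .augment import AugmentationConfig, augment, restrict_profile
from .evaluate import f1_binary, f1_macro, relabel_for_binary
from .io import CLASSES, EcgRecord
from .models import (
    BranchClassifier,
    ModelConfig,
    RCLSTMNet,
    build_model,
    forward_batch,
    predict_dataset,
)
from .nn import RAdam, Tensor
from .preprocess import oversample_to_balance

LOG_EPS = 1e-12


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 24
    lr0: float = 1e-3
    lr_decay_points: tuple[float, ...] = (0.25, 0.5, 0.75)
    lr_decay_factor: float = 0.1
    betas: tuple[float, float] = (0.9, 0.999)
    p_augment: float = 0.2
    class_weights: np.ndarray | None = None
    seed: int = 0
    oversample: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr0 <= 0:
            raise ValueError("epochs, batch_size, lr0 must be positive")
        pts = self.lr_decay_points
        if list(pts) != sorted(pts) or len(set(pts)) != len(pts) or not all(
                0 < p < 1 for p in pts):
            raise ValueError("decay points must be strictly increasing in (0,1)")


def weighted_cross_entropy(y_hat: np.ndarray, y: np.ndarray,
                           alpha: np.ndarray | None = None) -> float:
    """The class-weighted cross-entropy over a batch of softmax rows.

    ``y_hat``: (N, C) simplex rows; ``y``: (N, C) one-hot; ``alpha``: (C,)
    positive weights (defaults to ones). Logs are clamped at log(1e-12).
    """
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y_hat.ndim != 2:
        raise ValueError("y_hat and y must both be (N, C)")
    n, c = y_hat.shape
    alpha = np.ones(c) if alpha is None else np.asarray(alpha, dtype=float)
    if alpha.shape != (c,) or np.any(alpha <= 0):
        raise ValueError("alpha must be a positive length-C vector")
    logs = np.log(np.maximum(y_hat, LOG_EPS))
    return float(-(alpha[None, :] * y * logs).sum() / n)


def wce_loss(probs: Tensor, y_onehot: np.ndarray,
             alpha: np.ndarray | None = None) -> Tensor:
    """Autodiff version of :func:`weighted_cross_entropy` (same formula)."""
    n, c = probs.shape
    alpha = np.ones(c) if alpha is None else np.asarray(alpha, dtype=float)
    weights = (y_onehot * alpha[None, :]).astype(probs.data.dtype)
    return -(Tensor(weights) * probs.clip_min(LOG_EPS).log()).sum() * (1.0 / n)


def class_weights(label_counts: dict[str, int] | np.ndarray) -> np.ndarray:
    """Inverse-frequency weights alpha_i ~ total / (C * count_i),
    normalized to mean 1."""
    if isinstance(label_counts, dict):
        counts = np.array([label_counts[k] for k in sorted(
            label_counts, key=lambda c: CLASSES.index(c))], dtype=float)
    else:
        counts = np.asarray(label_counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("each class needs at least one example")
    alpha = counts.sum() / (counts.size * counts)
    return alpha / alpha.mean()


def lr_at(step: int, total_steps: int, config: TrainConfig) -> float:
    """Piecewise-constant schedule: lr0 * factor^k after k decay points."""
    if not 0 <= step < total_steps:
        raise ValueError("need 0 <= step < total_steps")
    k = sum(step >= p * total_steps for p in config.lr_decay_points)
    return config.lr0 * config.lr_decay_factor**k


def _labels_to_onehot(records: list[EcgRecord], n_classes: int) -> np.ndarray:
    space = CLASSES[:n_classes]
    idx = []
    for rec in records:
        if rec.label not in space:
            raise ValueError(
                f"record {rec.record_id} has label {rec.label!r}, expected "
                f"one of {space}")
        idx.append(space.index(rec.label))
    out = np.zeros((len(records), n_classes))
    out[np.arange(len(records)), idx] = 1.0
    return out


def _val_f1(model, val_records: list[EcgRecord]) -> float:
    preds = predict_dataset(model, val_records)
    pred_entries = [(p.record_id, p.label) for p in preds]
    ref_entries = [(r.record_id, r.label) for r in val_records]
    if model.config.n_classes == 2:
        return f1_binary(relabel_for_binary(pred_entries, ref_entries))
    return f1_macro(pred_entries, ref_entries)


def fit(model, train_records: list[EcgRecord],
        val_records: list[EcgRecord] | None,
        config: TrainConfig,
        augment_config: AugmentationConfig | None = None,
        trainable_params: list | None = None) -> tuple[object, list[dict]]:
    """End-to-end training loop; returns (model at best-val-F1, history).

    Oversampling is applied to the training split only; augmentation fires
    on-the-fly. With no validation split the final weights are kept.
    ``trainable_params`` restricts the optimizer (used by the staged
    recipe's frozen-branch stage).
    """
    if not train_records:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    if config.oversample:
        train_records = oversample_to_balance(train_records, rng)
    if augment_config is not None:
        augment_config = replace(augment_config, p_apply=config.p_augment)
    params = trainable_params if trainable_params is not None else model.parameters()
    opt = RAdam(params, lr=config.lr0, betas=config.betas)
    n = len(train_records)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    history: list[dict] = []
    best = (-1.0, None)
    step = 0
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            batch = [train_records[i] for i in order[lo : lo + config.batch_size]]
            signals = None
            if augment_config is not None:
                signals = [augment(rec.signal, rec.fs, augment_config, rng)
                           for rec in batch]
            probs = forward_batch(model, batch, signals=signals)
            y = _labels_to_onehot(batch, model.config.n_classes)
            loss = wce_loss(probs, y, config.class_weights)
            opt.zero_grad()
            loss.backward()
            opt.lr = lr_at(step, total_steps, config)
            opt.step()
            losses.append(float(loss.data))
            step += 1
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_records:
            entry["val_f1"] = _val_f1(model, val_records)
            if entry["val_f1"] > best[0]:
                best = (entry["val_f1"], model.state_dict())
        history.append(entry)
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def fit_rclstm_staged(model: RCLSTMNet,
                      datasets: dict[str, list[EcgRecord]],
                      config: TrainConfig,
                      augment_config: AugmentationConfig | None = None,
                      val_records: list[EcgRecord] | None = None) -> RCLSTMNet:
    """Three-stage recipe for the two-branch network.

    ``datasets`` keys: ``resnet_pretrain`` (long-recording stand-in for the
    Holter pretraining corpus), ``beat_pretrain`` (beat-morphology corpus
    stand-in), ``finetune`` (the target dataset). Missing stage datasets
    are skipped with a warning. The final stage freezes both branches and
    tunes only the fusion head for exactly one epoch.
    """
    if augment_config is not None:
        augment_config = restrict_profile(augment_config, "rclstm")
    n_classes = model.config.n_classes

    def stage(name, wrapper, records, epochs=None, trainable=None):
        if not records:
            warnings.warn(f"stage {name!r}: no dataset, skipped")
            return
        cfg = config if epochs is None else replace(config, epochs=epochs)
        fit(wrapper, records, val_records, cfg, augment_config,
            trainable_params=trainable)

    # stage 1: global branch alone
    stage("resnet_pretrain",
          _wrap_branch(model, "resnet", n_classes),
          datasets.get("resnet_pretrain"))
    # stage 2: beat CNN first (feature representation), then the full CLSTM
    beat_wrapper = _wrap_branch(model, "clstm", n_classes)
    cnn_params = [p for m in model.clstm.convs for p in m.parameters()]
    cnn_params += model.clstm.to_feat.parameters() + beat_wrapper.head.parameters()
    stage("beat_pretrain", beat_wrapper, datasets.get("beat_pretrain"),
          trainable=cnn_params)
    stage("clstm_train",
          _wrap_branch(model, "clstm", n_classes),
          datasets.get("finetune"))
    # stage 3: freeze branches, tune the fusion head for one epoch
    finetune = datasets.get("finetune")
    if finetune:
        head_params = model.head.parameters()
        fit(model, finetune, val_records,
            replace(config, epochs=1), augment_config,
            trainable_params=head_params)
    else:
        warnings.warn("stage 'fusion_head': no dataset, skipped")
    return model


class _BranchModel(BranchClassifier):
    """Adapter so a single branch accepts full featurized batches."""

    def __init__(self, parent: RCLSTMNet, which: str, n_classes: int):
        branch = parent.resnet if which == "resnet" else parent.clstm
        super().__init__(branch, n_classes)
        self.which = which
        self.config = parent.config
        self.family = "rclstm"

    def forward(self, signal, beats, n_beats):
        if self.which == "resnet":
            return super().forward(Tensor(signal[:, None, :].astype(nn.DTYPE)))
        return super().forward(beats, n_beats)


def _wrap_branch(model: RCLSTMNet, which: str, n_classes: int) -> _BranchModel:
    return _BranchModel(model, which, n_classes)


def cross_validate(config: ModelConfig, records: list[EcgRecord], k: int = 4,
                   train_config: TrainConfig | None = None,
                   augment_config: AugmentationConfig | None = None) -> dict:
    """Stratified k-fold cross-validation; reports per-fold and mean F1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    train_config = train_config or TrainConfig(epochs=5)
    labels = [rec.label for rec in records]
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=train_config.seed)
    fold_f1, folds = [], []
    for train_idx, val_idx in skf.split(np.zeros(len(records)), labels):
        nn.seed_init(train_config.seed)
        model = build_model(config)
        train_split = [records[i] for i in train_idx]
        val_split = [records[i] for i in val_idx]
        model, _ = fit(model, train_split, val_split, train_config,
                       augment_config)
        fold_f1.append(_val_f1(model, val_split))
        folds.append((train_idx, val_idx))
    return {
        "fold_f1": fold_f1,
        "mean_f1": float(np.mean(fold_f1)),
        "std_f1": float(np.std(fold_f1)),
        "folds": folds,
    }
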