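"""Neural architectures for single-lead ECG classification, plus the
beat-interval baseline, behind a uniform prediction interface.

Three families:

* **ECG-DualNet** — an LSTM signal encoder produces one latent vector; a
  five-block residual CNN encodes the log-spectrogram, with the latent
  vector injected into every block through conditional batch normalization
  (CBN). Each block halves the time-frequency resolution.
* **ECG-DualNet++** — the signal encoder is a Transformer (mean-pooled to
  the latent vector); the spectrogram tail is two residual blocks followed
  by three axial-attention blocks (attention along the time axis, then the
  frequency axis), all with CBN.
* **ECG-RCLSTM-Net** — a 1-D residual CNN consumes the whole padded signal
  (global features) while a CNN-LSTM consumes the variable-length list of
  two-second beat segments (local features); the two feature vectors are
  concatenated into a fully connected classification head.

The **beat-interval baseline** thresholds the standard deviation of
successive R-peak intervals: irregular RR is the hallmark of AFib.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io import CLASSES, EcgRecord
from .nn import Tensor, concat, softmax, stack
from .preprocess import (
    SPEC_BINS,
    SPEC_HOP,
    SPEC_WIN,
    TARGET_LEN,
    detect_r_peaks,
    fir_bandpass,
    log_spectrogram,
    pad_or_crop,
    segment_beats,
    standardize,
)

FAMILIES = ("dualnet", "dualnet_pp", "rclstm", "baseline")
SIZES = ("S", "M", "L", "XL")

#: Default BBI-threshold (seconds) on the s.d. of successive RR intervals.
DEFAULT_BBI_THRESHOLD = 0.1

#: Maximum number of beat segments fed to the CLSTM branch (longest records).
MAX_BEATS = 60

_DUALNET_SIZES = {
    #        latent  lstm_hidden  spectrogram channels (5 blocks)
    "S": dict(latent=128, hidden=128, channels=(32, 64, 128, 256, 256)),
    "M": dict(latent=192, hidden=192, channels=(48, 96, 192, 384, 384)),
    "L": dict(latent=288, hidden=288, channels=(64, 128, 256, 512, 512)),
    "XL": dict(latent=432, hidden=432, channels=(96, 192, 384, 768, 768)),
}

_DUALNET_PP_SIZES = {
    "S": dict(latent=128, d_model=96, heads=4, depth=2,
              res_channels=(32, 64), axial_channels=(96, 128, 160)),
    "M": dict(latent=192, d_model=128, heads=4, depth=3,
              res_channels=(48, 96), axial_channels=(128, 192, 256)),
    "L": dict(latent=288, d_model=192, heads=6, depth=4,
              res_channels=(64, 128), axial_channels=(192, 288, 384)),
    "XL": dict(latent=432, d_model=256, heads=8, depth=6,
               res_channels=(96, 192), axial_channels=(256, 384, 512)),
    "130m": dict(latent=512, d_model=896, heads=14, depth=12,
                 res_channels=(256, 512), axial_channels=(1024, 1280, 1536),
                 axial_heads=16),
}

_RCLSTM_SIZES = {
    "S": dict(stem=16, res_channels=(32, 64, 128), lstm_hidden=64,
              beat_channels=(16, 32), beat_feat=32),
    "M": dict(stem=32, res_channels=(64, 128, 256), lstm_hidden=96,
              beat_channels=(24, 48), beat_feat=48),
    "L": dict(stem=32, res_channels=(64, 128, 256, 512), lstm_hidden=128,
              beat_channels=(32, 64), beat_feat=64),
    # XL matches the published scale: ~30 M ResNet vs ~0.4 M CLSTM
    "XL": dict(stem=64, res_channels=(64, 128, 256, 512, 1024, 1024),
               lstm_hidden=256, beat_channels=(32, 64, 64), beat_feat=64),
}

_SIGNAL_FRAME = 64  # samples per LSTM/Transformer input step


@dataclass
class ModelConfig:
    """Architecture family + size tier + class count, with optional overrides."""

    family: str = "dualnet"
    size: str = "S"
    n_classes: int = 2
    target_len: int = TARGET_LEN
    fs: float = 300.0
    max_beats: int = MAX_BEATS
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        tables = {"dualnet": _DUALNET_SIZES, "dualnet_pp": _DUALNET_PP_SIZES,
                  "rclstm": _RCLSTM_SIZES}
        if self.family in tables and self.size not in tables[self.family]:
            raise ValueError(
                f"size {self.size!r} not available for {self.family}")

    def params(self) -> dict:
        tables = {"dualnet": _DUALNET_SIZES, "dualnet_pp": _DUALNET_PP_SIZES,
                  "rclstm": _RCLSTM_SIZES}
        base = dict(tables[self.family][self.size])
        base.update(self.overrides)
        return base


@dataclass
class Prediction:
    """Per-record class probabilities; label is the argmax class
    (ties break toward the lowest class index)."""

    record_id: str
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if abs(self.probs.sum() - 1.0) > 1e-6 or np.any(self.probs < 0):
            raise ValueError("probs must lie on the simplex")

    @property
    def label(self) -> str:
        return CLASSES[int(np.argmax(self.probs))]


# -- building blocks -----------------------------------------------------------


class ResBlockCBN(nn.Module):
    """Residual 2-D block: two 3x3 convs with CBN, stride-2 downsampling,
    1x1 projection skip."""

    def __init__(self, cin, cout, latent_dim, stride=2):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False)
        self.cbn1 = nn.ConditionalBatchNorm(cout, latent_dim)
        self.conv2 = nn.Conv2d(cout, cout, 3, stride=1, padding=1, bias=False)
        self.cbn2 = nn.ConditionalBatchNorm(cout, latent_dim)
        self.skip = nn.Conv2d(cin, cout, 1, stride=stride, bias=False)

    def forward(self, x, latent):
        y = self.cbn1(self.conv1(x), latent).relu()
        y = self.cbn2(self.conv2(y), latent)
        return (y + self.skip(x)).relu()


class ResBlock1d(nn.Module):
    def __init__(self, cin, cout, kernel=7, stride=2):
        super().__init__()
        pad = kernel // 2
        self.conv1 = nn.Conv1d(cin, cout, kernel, stride=stride, padding=pad,
                               bias=False)
        self.bn1 = nn.BatchNorm(cout)
        self.conv2 = nn.Conv1d(cout, cout, kernel, stride=1, padding=pad,
                               bias=False)
        self.bn2 = nn.BatchNorm(cout)
        self.skip = nn.Conv1d(cin, cout, 1, stride=stride, bias=False)

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (y + self.skip(x)).relu()


def _avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling (odd tails cropped)."""
    h, w = x.shape[2] & ~1, x.shape[3] & ~1
    x = x[:, :, :h, :w]
    return (x[:, :, ::2, ::2] + x[:, :, 1::2, ::2]
            + x[:, :, ::2, 1::2] + x[:, :, 1::2, 1::2]) * 0.25


class AxialBlockCBN(nn.Module):
    """Axial attention block: self-attention along the time axis, then the
    frequency axis, with per-axis positional embeddings, CBN conditioning,
    and 2x2 average-pool downsampling."""

    MAX_AXIS = 640

    def __init__(self, cin, cout, heads, latent_dim):
        super().__init__()
        self.proj = nn.Conv2d(cin, cout, 1, bias=False)
        self.pos_t = nn.normal_param((self.MAX_AXIS, cout))
        self.pos_f = nn.normal_param((self.MAX_AXIS, cout))
        self.attn_t = nn.MultiHeadSelfAttention(cout, heads)
        self.attn_f = nn.MultiHeadSelfAttention(cout, heads)
        self.cbn = nn.ConditionalBatchNorm(cout, latent_dim)

    def forward(self, x, latent):
        x = self.proj(x)
        n, c, h, w = x.shape
        # attention along time (width) axis
        seq = x.transpose(0, 2, 3, 1).reshape(n * h, w, c)
        seq = seq + self.attn_t(seq + self.pos_t[:w, :].reshape(1, w, c))
        x = seq.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        # attention along frequency (height) axis
        seq = x.transpose(0, 3, 2, 1).reshape(n * w, h, c)
        seq = seq + self.attn_f(seq + self.pos_f[:h, :].reshape(1, h, c))
        x = seq.reshape(n, w, h, c).transpose(0, 3, 2, 1)
        x = self.cbn(x, latent).relu()
        return _avg_pool2(x) if min(x.shape[2], x.shape[3]) >= 2 else x


def _frame_signal(signal: np.ndarray) -> np.ndarray:
    """(N, L) -> (N, T, frame): non-overlapping short sequences."""
    n, length = signal.shape
    t = length // _SIGNAL_FRAME
    return signal[:, : t * _SIGNAL_FRAME].reshape(n, t, _SIGNAL_FRAME)


class DualNet(nn.Module):
    """LSTM signal encoder + CBN-conditioned residual spectrogram encoder."""

    family = "dualnet"

    def __init__(self, config: ModelConfig):
        super().__init__()
        p = config.params()
        self.config = config
        self.lstm = nn.LSTM(_SIGNAL_FRAME, p["hidden"])
        self.to_latent = nn.Linear(p["hidden"], p["latent"])
        chans = p["channels"]
        self.blocks = [
            ResBlockCBN(cin, cout, p["latent"])
            for cin, cout in zip((1,) + tuple(chans[:-1]), chans)
        ]
        self.head = nn.Linear(chans[-1], config.n_classes)

    def encode_signal(self, signal: np.ndarray) -> Tensor:
        frames = Tensor(_frame_signal(signal).astype(nn.DTYPE))
        _, h = self.lstm(frames)
        return self.to_latent(h)

    def forward(self, signal: np.ndarray, spec: np.ndarray) -> Tensor:
        latent = self.encode_signal(signal)
        x = Tensor(spec[:, None, :, :].astype(nn.DTYPE))
        for block in self.blocks:
            x = block(x, latent)
        pooled = x.mean(axis=(2, 3))
        return softmax(self.head(pooled), axis=-1)


class DualNetPP(nn.Module):
    """Transformer signal encoder + ResNet/axial-attention spectrogram
    encoder, all CBN-conditioned."""

    family = "dualnet_pp"
    MAX_SEQ = 640

    def __init__(self, config: ModelConfig):
        super().__init__()
        p = config.params()
        self.config = config
        d = p["d_model"]
        self.embed = nn.Linear(_SIGNAL_FRAME, d)
        self.pos = nn.normal_param((self.MAX_SEQ, d))
        self.encoder = [nn.TransformerBlock(d, p["heads"])
                        for _ in range(p["depth"])]
        self.to_latent = nn.Linear(d, p["latent"])
        rc = p["res_channels"]
        self.res_blocks = [
            ResBlockCBN(cin, cout, p["latent"])
            for cin, cout in zip((1,) + tuple(rc[:-1]), rc)
        ]
        ac = p["axial_channels"]
        axial_heads = p.get("axial_heads", p["heads"])
        self.axial_blocks = [
            AxialBlockCBN(cin, cout, axial_heads, p["latent"])
            for cin, cout in zip((rc[-1],) + tuple(ac[:-1]), ac)
        ]
        self.head = nn.Linear(ac[-1], config.n_classes)

    def encode_signal(self, signal: np.ndarray) -> Tensor:
        frames = _frame_signal(signal)
        n, t, _ = frames.shape
        x = self.embed(Tensor(frames.astype(nn.DTYPE)))
        x = x + self.pos[:t, :].reshape(1, t, x.shape[2])
        for block in self.encoder:
            x = block(x)
        return self.to_latent(x.mean(axis=1))  # mean pooling over the sequence

    def forward(self, signal: np.ndarray, spec: np.ndarray) -> Tensor:
        latent = self.encode_signal(signal)
        x = Tensor(spec[:, None, :, :].astype(nn.DTYPE))
        for block in self.res_blocks:
            x = block(x, latent)
        for block in self.axial_blocks:
            x = block(x, latent)
        pooled = x.mean(axis=(2, 3))
        return softmax(self.head(pooled), axis=-1)


class ResNetBranch(nn.Module):
    """Global branch: 1-D residual CNN over the whole padded signal."""

    def __init__(self, stem: int, channels: tuple[int, ...]):
        super().__init__()
        self.stem = nn.Conv1d(1, stem, 15, stride=4, padding=7, bias=False)
        self.bn = nn.BatchNorm(stem)
        self.blocks = [ResBlock1d(cin, cout)
                       for cin, cout in zip((stem,) + tuple(channels[:-1]),
                                            channels)]
        self.feat_dim = channels[-1]

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.stem(x)).relu()
        for block in self.blocks:
            y = block(y)
        return y.mean(axis=2)


class CLSTMBranch(nn.Module):
    """Local branch: shared 1-D CNN per beat segment, LSTM over the beat
    sequence, summarized by the recurrent state at each record's true
    beat count. Records without any detected beat use a learned
    empty-sequence embedding."""

    def __init__(self, beat_channels: tuple[int, ...], beat_feat: int,
                 lstm_hidden: int):
        super().__init__()
        convs = []
        cin = 1
        for cout in beat_channels:
            convs.append(nn.Conv1d(cin, cout, 7, stride=3, padding=3))
            cin = cout
        self.convs = convs
        self.to_feat = nn.Linear(cin, beat_feat)
        self.lstm = nn.LSTM(beat_feat, lstm_hidden)
        self.empty = nn.Parameter(np.zeros(lstm_hidden))
        self.feat_dim = lstm_hidden

    def forward(self, beats: np.ndarray, n_beats: np.ndarray) -> Tensor:
        n, b, seg = beats.shape
        if b == 0 or int(np.max(n_beats)) == 0:
            return self.empty.reshape(1, self.feat_dim) * Tensor(
                np.ones((n, 1), dtype=nn.DTYPE))
        x = Tensor(beats.reshape(n * b, 1, seg).astype(nn.DTYPE))
        for conv in self.convs:
            x = conv(x).relu()
        feats = self.to_feat(x.mean(axis=2)).reshape(n, b, -1)
        outs, _ = self.lstm(feats)  # (N, B, H)
        # select the hidden state at each record's final real beat
        sel = np.zeros((n, b, 1), dtype=nn.DTYPE)
        has = n_beats > 0
        sel[np.arange(n)[has], np.maximum(n_beats[has] - 1, 0), 0] = 1.0
        summary = (outs * Tensor(sel)).sum(axis=1)
        empty_mask = Tensor((~has).astype(nn.DTYPE)[:, None])
        return summary + empty_mask * self.empty.reshape(1, self.feat_dim)


class RCLSTMNet(nn.Module):
    """ResNet (global) + CLSTM (local) with a fully connected fusion head."""

    family = "rclstm"

    def __init__(self, config: ModelConfig):
        super().__init__()
        p = config.params()
        self.config = config
        self.resnet = ResNetBranch(p["stem"], tuple(p["res_channels"]))
        self.clstm = CLSTMBranch(tuple(p["beat_channels"]), p["beat_feat"],
                                 p["lstm_hidden"])
        self.head = nn.Linear(self.resnet.feat_dim + self.clstm.feat_dim,
                              config.n_classes)

    def forward(self, signal: np.ndarray, beats: np.ndarray,
                n_beats: np.ndarray) -> Tensor:
        g = self.resnet(Tensor(signal[:, None, :].astype(nn.DTYPE)))
        l = self.clstm(beats, n_beats)
        fused = concat([g, l], axis=1)
        return softmax(self.head(fused), axis=-1)


class BranchClassifier(nn.Module):
    """A branch plus a temporary linear softmax head (for staged pretraining)."""

    def __init__(self, branch: nn.Module, n_classes: int):
        super().__init__()
        self.branch = branch
        self.head = nn.Linear(branch.feat_dim, n_classes)

    def forward(self, *inputs) -> Tensor:
        return softmax(self.head(self.branch(*inputs)), axis=-1)


# -- builders ------------------------------------------------------------------


def build_dualnet(config: ModelConfig) -> DualNet:
    if config.family != "dualnet":
        raise ValueError("config.family must be 'dualnet'")
    return DualNet(config)


def build_dualnet_pp(config: ModelConfig) -> DualNetPP:
    if config.family != "dualnet_pp":
        raise ValueError("config.family must be 'dualnet_pp'")
    return DualNetPP(config)


def build_rclstm(config: ModelConfig) -> RCLSTMNet:
    if config.family != "rclstm":
        raise ValueError("config.family must be 'rclstm'")
    return RCLSTMNet(config)


def build_model(config: ModelConfig) -> nn.Module:
    builders = {"dualnet": build_dualnet, "dualnet_pp": build_dualnet_pp,
                "rclstm": build_rclstm}
    return builders[config.family](config)


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


# -- featurization -------------------------------------------------------------


def spectrogram_frames(target_len: int) -> int:
    return (target_len - SPEC_WIN) // SPEC_HOP + 1


def featurize_dualnet(records: list[EcgRecord], target_len: int,
                      signals: list[np.ndarray] | None = None):
    """Standardize, compute log-spectrograms, and pad both representations.

    Returns (signal batch (N, target_len), spectrogram batch (N, 64, F)).
    ``signals`` overrides the stored record signals (augmented copies).
    """
    f_target = spectrogram_frames(target_len)
    sigs, specs = [], []
    for i, rec in enumerate(records):
        x = signals[i] if signals is not None else rec.signal
        s = standardize(x)
        padded_for_spec = s if s.size >= SPEC_WIN else pad_or_crop(s, SPEC_WIN)
        sp = log_spectrogram(padded_for_spec).values
        if sp.shape[1] < f_target:
            sp = np.pad(sp, ((0, 0), (0, f_target - sp.shape[1])))
        elif sp.shape[1] > f_target:
            start = (sp.shape[1] - f_target) // 2
            sp = sp[:, start : start + f_target]
        sigs.append(pad_or_crop(s, target_len))
        specs.append(sp)
    return np.stack(sigs), np.stack(specs)


def featurize_rclstm(records: list[EcgRecord], target_len: int, fs: float,
                     max_beats: int = MAX_BEATS,
                     signals: list[np.ndarray] | None = None):
    """Bandpass, standardize, detect beats, and assemble the two branch inputs.

    Returns (signal batch, beat batch (N, max_beats, 2*fs), beat counts).
    """
    seg_len = 2 * int(fs)
    sigs, beat_arrs, counts = [], [], []
    for i, rec in enumerate(records):
        x = signals[i] if signals is not None else rec.signal
        s = standardize(fir_bandpass(x, rec.fs))
        peaks = detect_r_peaks(s, rec.fs)
        segs = segment_beats(s, peaks, fs)[:max_beats]
        arr = np.zeros((max_beats, seg_len))
        for j, seg in enumerate(segs):
            arr[j] = seg.values
        sigs.append(pad_or_crop(s, target_len))
        beat_arrs.append(arr)
        counts.append(len(segs))
    return np.stack(sigs), np.stack(beat_arrs), np.array(counts, dtype=int)


def forward_batch(model: nn.Module, records: list[EcgRecord],
                  signals: list[np.ndarray] | None = None) -> Tensor:
    """Featurize per the model family and run one forward pass."""
    cfg = model.config
    if model.family in ("dualnet", "dualnet_pp"):
        sig, spec = featurize_dualnet(records, cfg.target_len, signals)
        return model(sig, spec)
    sig, beats, counts = featurize_rclstm(records, cfg.target_len, cfg.fs,
                                          cfg.max_beats, signals)
    return model(sig, beats, counts)


# -- baseline ------------------------------------------------------------------


def baseline_bbi(record: EcgRecord,
                 threshold: float = DEFAULT_BBI_THRESHOLD) -> Prediction:
    """Classify AFib vs NSR on the standard deviation of beat-to-beat
    intervals. Fewer than 3 detected peaks defaults to NSR."""
    peaks = detect_r_peaks(record.signal, record.fs)
    if peaks.size < 3:
        return Prediction(record.record_id, [1.0, 0.0])
    bbi = np.diff(peaks) / record.fs
    is_afib = float(np.std(bbi)) > threshold
    return Prediction(record.record_id, [0.0, 1.0] if is_afib else [1.0, 0.0])


def predict_dataset(model: nn.Module, records: list[EcgRecord],
                    batch_size: int = 32) -> list[Prediction]:
    """Deterministic inference: one Prediction per record, order preserved,
    augmentation disabled."""
    model.eval()
    preds: list[Prediction] = []
    for lo in range(0, len(records), batch_size):
        chunk = records[lo : lo + batch_size]
        probs = forward_batch(model, chunk).data
        probs = probs / probs.sum(axis=1, keepdims=True)
        preds.extend(Prediction(rec.record_id, row)
                     for rec, row in zip(chunk, probs))
    return preds
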