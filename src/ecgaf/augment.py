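"""Stochastic ECG augmentation: ten operators, each fired independently.

Operators (applied in this fixed order when they fire):

1.  ``dropping`` — zero exactly ``ceil(drop_fraction * L)`` random samples;
2.  ``cutout`` — zero one contiguous random run;
3.  ``resampling`` — resample the whole signal by a random factor
    (emulates a different heart rate; the one length-changing operator);
4.  ``random_resampling`` — resample along a smooth random monotone
    time-warp (changing heart rate), length preserved;
5.  ``scaling`` — pointwise multiply by a random factor;
6.  ``shifting`` — circular shift by a random offset;
7.  ``sine_addition`` — add a sinusoid with random magnitude/frequency/phase;
8.  ``artificial_noise`` — add white Gaussian noise;
9.  ``window_warping`` — stretch/compress one random window, then restore
    the original length (right-pad with zeros or right-crop);
10. ``bandpass`` — the FIR bandpass of :mod:`ecgaf.preprocess`.

Default parameter ranges are chosen to preserve rhythm-class semantics:
no operator converts regular NSR beat statistics into AFib-like
irregularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import DEFAULT_BAND, fir_bandpass

OP_ORDER = (
    "dropping",
    "cutout",
    "resampling",
    "random_resampling",
    "scaling",
    "shifting",
    "sine_addition",
    "artificial_noise",
    "window_warping",
    "bandpass",
)

#: Operator subsets per architecture family.
PROFILES = {
    "dualnet": OP_ORDER,
    "rclstm": ("resampling", "artificial_noise", "window_warping"),
}


def _check_range(name, rng_pair):
    lo, hi = rng_pair
    if lo > hi:
        raise ValueError(f"{name} range is not well-ordered: {rng_pair}")


@dataclass(frozen=True)
class AugmentationConfig:
    """Per-operator parameter ranges + a global per-operator firing probability."""

    p_apply: float = 0.2
    drop_fraction: float = 0.05
    cutout_frac_range: tuple[float, float] = (0.01, 0.10)
    resample_factor_range: tuple[float, float] = (0.8, 1.2)
    elastic_strength: float = 0.15
    elastic_knots: int = 10
    scale_range: tuple[float, float] = (0.7, 1.3)
    shift_max_frac: float = 0.25
    sine_amp_frac: float = 0.3
    sine_freq_range: tuple[float, float] = (0.1, 2.0)
    noise_sigma_frac_range: tuple[float, float] = (0.0, 0.1)
    warp_window_frac: float = 0.10
    warp_factor_range: tuple[float, float] = (0.5, 2.0)
    band: tuple[float, float] = DEFAULT_BAND
    enabled_ops: tuple[str, ...] = OP_ORDER

    def __post_init__(self):
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must be in [0, 1]")
        if not 0.0 <= self.drop_fraction <= 1.0:
            raise ValueError("drop_fraction must be in [0, 1]")
        for name in ("cutout_frac_range", "resample_factor_range", "scale_range",
                     "sine_freq_range", "noise_sigma_frac_range",
                     "warp_factor_range", "band"):
            _check_range(name, getattr(self, name))
        unknown = set(self.enabled_ops) - set(OP_ORDER)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")


def restrict_profile(config: AugmentationConfig,
                     profile: str) -> AugmentationConfig:
    """Confine the operator set to an architecture family's profile."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    return replace(config, enabled_ops=PROFILES[profile])


# -- individual operators ------------------------------------------------------


def _dropping(x, fs, cfg, rng):
    k = int(np.ceil(cfg.drop_fraction * x.size))
    idx = rng.choice(x.size, size=min(k, x.size), replace=False)
    y = x.copy()
    y[idx] = 0.0
    return y


def _cutout(x, fs, cfg, rng):
    lo, hi = cfg.cutout_frac_range
    length = max(1, int(round(rng.uniform(lo, hi) * x.size)))
    start = int(rng.integers(0, max(1, x.size - length + 1)))
    y = x.copy()
    y[start : start + length] = 0.0
    return y


def _resampling(x, fs, cfg, rng):
    factor = rng.uniform(*cfg.resample_factor_range)
    new_len = max(2, int(round(x.size * factor)))
    return np.interp(np.linspace(0.0, x.size - 1.0, new_len),
                     np.arange(x.size), x)


def _random_resampling(x, fs, cfg, rng):
    # smooth log-speed profile from a few knots -> monotone warp, same length
    knots = rng.normal(0.0, cfg.elastic_strength, size=max(2, cfg.elastic_knots))
    speed = np.exp(np.interp(np.linspace(0, 1, x.size),
                             np.linspace(0, 1, knots.size), knots))
    pos = np.concatenate([[0.0], np.cumsum(speed)[:-1]])
    pos *= (x.size - 1.0) / pos[-1]
    return np.interp(pos, np.arange(x.size), x)


def _scaling(x, fs, cfg, rng):
    return x * rng.uniform(*cfg.scale_range)


def _shifting(x, fs, cfg, rng):
    max_shift = max(1, int(cfg.shift_max_frac * x.size))
    return np.roll(x, int(rng.integers(-max_shift, max_shift + 1)))


def _sine_addition(x, fs, cfg, rng):
    amp = rng.uniform(0.0, cfg.sine_amp_frac) * (x.std() or 1.0)
    freq = rng.uniform(*cfg.sine_freq_range)
    phase = rng.uniform(0.0, 2 * np.pi)
    t = np.arange(x.size) / fs
    return x + amp * np.sin(2 * np.pi * freq * t + phase)


def _artificial_noise(x, fs, cfg, rng):
    sigma = rng.uniform(*cfg.noise_sigma_frac_range) * (x.std() or 1.0)
    return x + rng.normal(0.0, sigma, size=x.size)


def _window_warping(x, fs, cfg, rng):
    n = x.size
    w = max(2, int(round(cfg.warp_window_frac * n)))
    start = int(rng.integers(0, max(1, n - w + 1)))
    factor = rng.uniform(*cfg.warp_factor_range)
    new_w = max(2, int(round(w * factor)))
    warped = np.interp(np.linspace(0.0, w - 1.0, new_w),
                       np.arange(w), x[start : start + w])
    y = np.concatenate([x[:start], warped, x[start + w :]])
    if y.size >= n:
        return y[:n]
    return np.concatenate([y, np.zeros(n - y.size)])


def _bandpass(x, fs, cfg, rng):
    return fir_bandpass(x, fs, *cfg.band)


_OPERATORS = {
    "dropping": _dropping,
    "cutout": _cutout,
    "resampling": _resampling,
    "random_resampling": _random_resampling,
    "scaling": _scaling,
    "shifting": _shifting,
    "sine_addition": _sine_addition,
    "artificial_noise": _artificial_noise,
    "window_warping": _window_warping,
    "bandpass": _bandpass,
}


def apply_operator(name: str, signal: np.ndarray, fs: float,
                   config: AugmentationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Apply one named operator unconditionally (no firing coin)."""
    if name not in _OPERATORS:
        raise ValueError(f"unknown operator {name!r}")
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return _OPERATORS[name](x, fs, config, rng)


def augment(signal: np.ndarray, fs: float, config: AugmentationConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Fire each enabled operator independently with probability ``p_apply``,
    in the fixed :data:`OP_ORDER`. Deterministic for a fixed rng state."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    for name in OP_ORDER:
        if name in config.enabled_ops and rng.random() < config.p_apply:
            x = _OPERATORS[name](x, fs, config, rng)
    return x
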