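"""Sliding-window segmentation and supervised dataset assembly.

Analysis windows of ``window_ms`` (default 1000 ms) advance in ``step_ms``
(default 200 ms) increments, so consecutive windows overlap by 800 ms and a
fresh estimate is available well inside a 300 ms perceptual latency budget.
Each window is divided into ``seq_len`` equal sub-windows (20 x 50 ms at the
defaults); the per-sub-window mean of every envelope channel forms one step
of the model's input sequence, and the same sub-window means of the target
channels form the aligned output sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import SignalTrace, ValidationError


@dataclass
class WindowingConfig:
    window_ms: float = 1000.0
    step_ms: float = 200.0
    seq_len: int = 20
    out_len: int = 20
    latency_budget_ms: float = 300.0  # documentation only

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValidationError("window_ms and step_ms must be positive")
        if self.step_ms > self.window_ms:
            raise ValidationError("step_ms must not exceed window_ms")
        if self.seq_len < 1 or self.out_len < 1:
            raise ValidationError("seq_len and out_len must be >= 1")

    def window_samples(self, rate_hz: float) -> int:
        w = self.window_ms * rate_hz / 1000.0
        if abs(w - round(w)) > 1e-9:
            raise ValidationError("window_ms must be a whole number of samples")
        return int(round(w))

    def step_samples(self, rate_hz: float) -> int:
        s = self.step_ms * rate_hz / 1000.0
        if abs(s - round(s)) > 1e-9:
            raise ValidationError("step_ms must be a whole number of samples")
        return int(round(s))


@dataclass
class SupervisedDataset:
    """Windowed feature sequences with aligned target sequences.

    ``X`` is (n_examples, seq_len, n_features), ``y`` is (n_examples,
    out_len, n_targets), ``mask`` marks valid sequence positions (padding
    positions are zero in ``X``).  ``window_starts`` records each example's
    first source sample, which the block splitter uses to reason about
    overlap.
    """

    X: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    target_names: list[str] = field(default_factory=list)
    window_starts: np.ndarray | None = None
    window_samples: int = 0  # source-sample span of one window (0 = unknown)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.X.ndim != 3 or self.y.ndim != 3 or self.mask.ndim != 2:
            raise ValidationError("X, y must be 3-D and mask 2-D")
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != self.mask.shape[0]:
            raise ValidationError("X, y and mask disagree on n_examples")
        if self.mask.shape[1] != self.X.shape[1]:
            raise ValidationError("mask length must equal seq_len")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValidationError("dataset contains NaN")
        if np.any(self.X[~self.mask] != 0):
            raise ValidationError("padded (mask=False) positions must be zero in X")

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "SupervisedDataset":
        return SupervisedDataset(
            self.X[idx],
            self.y[idx],
            self.mask[idx],
            self.feature_names,
            self.target_names,
            None if self.window_starts is None else self.window_starts[idx],
            self.window_samples,
        )


def count_windows(n_samples: int, rate_hz: float, config: WindowingConfig) -> int:
    """Number of full windows: ``floor((n - w) / s) + 1``, or 0 if too short."""
    w = config.window_samples(rate_hz)
    s = config.step_samples(rate_hz)
    if n_samples < w:
        return 0
    return (n_samples - w) // s + 1


def build_dataset(
    features: SignalTrace, targets: SignalTrace, config: WindowingConfig | None = None
) -> SupervisedDataset:
    """Window ``features`` and ``targets`` into aligned mean sequences.

    Every window contributes one example: sub-window means of each feature
    channel (shape ``seq_len x n_features``) and sub-window means of each
    target channel over the same span (``out_len x n_targets``).
    """
    cfg = config or WindowingConfig()
    if features.rate_hz != targets.rate_hz:
        raise ValidationError("features and targets disagree on rate_hz")
    if features.n_samples != targets.n_samples:
        raise ValidationError("features and targets disagree on n_samples")
    rate = features.rate_hz
    w = cfg.window_samples(rate)
    s = cfg.step_samples(rate)
    if w % cfg.seq_len:
        raise ValidationError(
            f"window of {w} samples not divisible into {cfg.seq_len} sub-windows"
        )
    if cfg.out_len != cfg.seq_len and w % cfg.out_len:
        raise ValidationError(
            f"window of {w} samples not divisible into {cfg.out_len} target bins"
        )
    n_win = count_windows(features.n_samples, rate, cfg)
    starts = np.arange(n_win) * s

    def window_means(trace: SignalTrace, n_bins: int) -> np.ndarray:
        sub = w // n_bins
        out = np.empty((n_win, n_bins, trace.n_channels))
        for i, st in enumerate(starts):
            seg = trace.samples[:, st : st + w]  # (C, w)
            out[i] = seg.reshape(trace.n_channels, n_bins, sub).mean(axis=2).T
        return out

    X = window_means(features, cfg.seq_len)
    y = window_means(targets, cfg.out_len)
    mask = np.ones((n_win, cfg.seq_len), dtype=bool)
    return SupervisedDataset(
        X,
        y,
        mask,
        feature_names=list(features.channel_names),
        target_names=list(targets.channel_names),
        window_starts=starts,
        window_samples=w,
    )


def make_padding_mask(lengths: np.ndarray, seq_len: int) -> np.ndarray:
    """Boolean mask (n, seq_len): True for positions below each length."""
    lengths = np.asarray(lengths, dtype=int)
    if np.any(lengths < 0) or np.any(lengths > seq_len):
        raise ValidationError("lengths must lie in [0, seq_len]")
    return np.arange(seq_len)[None, :] < lengths[:, None]


def split_dataset(
    ds: SupervisedDataset,
    test_fraction: float,
    scheme: str = "by_block",
    seed: int = 0,
) -> tuple[SupervisedDataset, SupervisedDataset]:
    """Split into disjoint train/test subsets.

    ``by_example`` samples test examples uniformly; ``by_block`` holds out
    one contiguous span of window indices and additionally drops from the
    train side any window overlapping the held-out span in source time, so
    the 800 ms window overlap cannot leak test samples into training.
    """
    if not (0 < test_fraction < 1):
        raise ValidationError("test_fraction must be in (0, 1)")
    n = ds.n_examples
    n_test = max(1, int(round(n * test_fraction)))
    if n_test >= n:
        raise ValidationError("test fraction leaves no training examples")
    rng = np.random.default_rng(seed)
    if scheme == "by_example":
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
    elif scheme == "by_block":
        start = int(rng.integers(0, n - n_test + 1))
        test_idx = np.arange(start, start + n_test)
        keep = np.ones(n, dtype=bool)
        keep[test_idx] = False
        if ds.window_starts is not None and ds.window_samples > 0:
            # drop any train window that shares source samples with the block
            span = ds.window_samples
            test_lo = ds.window_starts[test_idx[0]]
            test_hi = ds.window_starts[test_idx[-1]] + span
            overlap = (ds.window_starts + span > test_lo) & (
                ds.window_starts < test_hi
            )
            keep &= ~overlap
        train_idx = np.flatnonzero(keep)
        if train_idx.size == 0:
            raise ValidationError("block split leaves no training examples")
    else:
        raise ValidationError(f"unknown split scheme {scheme!r}")
    return ds.subset(train_idx), ds.subset(test_idx)
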