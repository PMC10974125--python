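"""Sequence estimators and the R² evaluation harness.

The primary estimator is an encoder-only transformer: the 8-dimensional
envelope feature sequence (plus sinusoidal position embeddings) is passed
through a stack of self-attention encoder layers, and a final fully connected
layer projects the flattened encoder output to the target sequence shape.
Attention runs at width ``d_model == n_features`` (no input up-projection by
default), so the head count must divide the feature count.  Vanilla RNN and
LSTM estimators with the same output head serve as baselines; all three train
with Adam on mean-squared error under one seeding protocol.

Evaluation reports the coefficient of determination R² per trial and
summarises trials as highest / lowest / mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .trace import ValidationError
from .windowing import SupervisedDataset


@dataclass
class TransformerConfig:
    """Hyperparameters shared by all estimators.

    ``n_features`` doubles as the attention width (d_model); ``d_ff`` is the
    feedforward width for the transformer and the hidden width for the
    recurrent baselines.
    """

    n_features: int = 8
    n_targets: int = 3
    seq_len: int = 20
    out_len: int = 20
    n_heads: int = 2
    n_layers: int = 1
    d_ff: int = 64
    dropout: float = 0.1
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features % self.n_heads:
            raise ValidationError(
                f"n_features={self.n_features} must be divisible by "
                f"n_heads={self.n_heads}"
            )
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")


@dataclass
class EvalReport:
    """Per-trial R² with the highest/lowest/mean summary convention."""

    r2_per_trial: list[float]
    highest: float
    lowest: float
    mean: float
    model_name: str = ""
    signal_mode: str = "fusion"  # {fusion, mmg_only}
    #: mean-over-trials R² of each target axis (supplementary breakdown)
    r2_per_axis: list[float] | None = None

    @classmethod
    def from_scores(
        cls,
        scores: list[float],
        model_name: str = "",
        signal_mode: str = "fusion",
        per_axis: list[float] | None = None,
    ) -> "EvalReport":
        if not scores:
            raise ValidationError("no trial scores to report")
        return cls(
            r2_per_trial=list(scores),
            highest=float(max(scores)),
            lowest=float(min(scores)),
            mean=float(np.mean(scores)),
            model_name=model_name,
            signal_mode=signal_mode,
            r2_per_axis=per_axis,
        )

    def as_dict(self) -> dict:
        return {
            "model": self.model_name,
            "signal_mode": self.signal_mode,
            "highest": self.highest,
            "lowest": self.lowest,
            "mean": self.mean,
            "r2_per_trial": self.r2_per_trial,
            "r2_per_axis": self.r2_per_axis,
        }


def position_embedding(max_len: int, d_pos: int) -> np.ndarray:
    """Sinusoidal position table: sin on even slots, cos on odd slots.

    ``PE[p, 2i] = sin(p / 10000^(2i/d_pos))``,
    ``PE[p, 2i+1] = cos(p / 10000^(2i/d_pos))``; every entry lies in [-1, 1].
    """
    if d_pos < 1:
        raise ValidationError("d_pos must be >= 1")
    table = np.zeros((max_len, d_pos))
    pos = np.arange(max_len)[:, None]
    i2 = np.arange(0, d_pos, 2)
    denom = 10000.0 ** (i2 / d_pos)
    table[:, 0::2] = np.sin(pos / denom)
    if d_pos > 1:
        table[:, 1::2] = np.cos(pos / denom[: table[:, 1::2].shape[1]])
    return table


class _EstimatorBase(nn.Module):
    """Shared output head and target-scaling bookkeeping."""

    config: TransformerConfig
    name: str = ""

    def _init_head(self, d_enc: int, rng: np.random.Generator) -> None:
        c = self.config
        self.head = nn.Linear(c.seq_len * d_enc, c.out_len * c.n_targets, rng)
        # target standardisation fitted by the trainer (identity until then)
        self.y_mean = np.zeros(c.n_targets)
        self.y_std = np.ones(c.n_targets)

    def _project(self, h: np.ndarray) -> np.ndarray:
        b = h.shape[0]
        out = self.head.forward(h.reshape(b, -1))
        return out.reshape(b, self.config.out_len, self.config.n_targets)

    def _project_backward(self, dpred: np.ndarray) -> np.ndarray:
        b = dpred.shape[0]
        dflat = self.head.backward(dpred.reshape(b, -1))
        return dflat.reshape(b, self.config.seq_len, -1)

    def predict(self, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Deterministic (eval-mode) prediction on the original target scale."""
        scaled = self.forward(X, mask, train=False, rng=None)
        return scaled * self.y_std + self.y_mean


class TransformerEstimator(_EstimatorBase):
    """Encoder-only transformer for sequence-to-sequence regression."""

    name = "transformer"

    def __init__(self, config: TransformerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.n_features
        self.pe = position_embedding(config.seq_len, d)
        self.layers = [
            nn.EncoderLayer(d, config.n_heads, config.d_ff, config.dropout, rng)
            for _ in range(config.n_layers)
        ]
        self._init_head(d, rng)

    def forward(
        self,
        X: np.ndarray,
        mask: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        if X.ndim != 3 or X.shape[2] != self.config.n_features:
            raise ValidationError(
                f"expected input (batch, {self.config.seq_len}, "
                f"{self.config.n_features}), got {X.shape}"
            )
        h = X + self.pe[: X.shape[1]]
        for layer in self.layers:
            h = layer.forward(h, mask, train, rng)
        return self._project(h)

    def backward(self, dpred: np.ndarray) -> np.ndarray:
        dh = self._project_backward(dpred)
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dh


class RecurrentEstimator(_EstimatorBase):
    """RNN / LSTM baseline: recurrent encoder, same flatten-project head."""

    def __init__(self, config: TransformerConfig, cell: str = "rnn"):
        self.config = config
        self.name = cell
        rng = np.random.default_rng(config.seed)
        if cell == "rnn":
            self.rnn = nn.RNNCellSequence(config.n_features, config.d_ff, rng)
        elif cell == "lstm":
            self.rnn = nn.LSTMCellSequence(config.n_features, config.d_ff, rng)
        else:
            raise ValidationError(f"unknown cell {cell!r}")
        self._init_head(config.d_ff, rng)

    def forward(
        self,
        X: np.ndarray,
        mask: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        if X.ndim != 3 or X.shape[2] != self.config.n_features:
            raise ValidationError(f"bad input shape {X.shape}")
        if mask is not None:
            X = X * mask[:, :, None]
        return self._project(self.rnn.forward(X))

    def backward(self, dpred: np.ndarray) -> np.ndarray:
        return self.rnn.backward(self._project_backward(dpred))


def make_estimator(kind: str, config: TransformerConfig) -> _EstimatorBase:
    if kind == "transformer":
        return TransformerEstimator(config)
    if kind in ("rnn", "lstm"):
        return RecurrentEstimator(config, cell=kind)
    raise ValidationError(f"unknown estimator kind {kind!r}")


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def train_estimator(
    model: _EstimatorBase,
    train: SupervisedDataset,
    val: SupervisedDataset | None = None,
) -> dict:
    """Train ``model`` in place by mini-batch Adam on MSE.

    Targets are standardised with training-set statistics (stored on the
    model and inverted by :meth:`predict`).  Per-epoch train/val losses are
    recorded and the best-validation parameters are restored at the end.
    Returns the loss history dict.
    """
    c = model.config
    if train.n_examples == 0:
        raise ValidationError("empty training set")
    rng = np.random.default_rng(c.seed)
    model.y_mean = train.y.reshape(-1, c.n_targets).mean(axis=0)
    model.y_std = train.y.reshape(-1, c.n_targets).std(axis=0)
    model.y_std[model.y_std <= 0] = 1.0
    y_train = (train.y - model.y_mean) / model.y_std
    y_val = None if val is None else (val.y - model.y_mean) / model.y_std

    opt = nn.Adam(model.parameters(), lr=c.lr)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state_dict()
    for _ in range(c.epochs):
        order = rng.permutation(train.n_examples)
        epoch_loss = 0.0
        for start in range(0, train.n_examples, c.batch_size):
            idx = order[start : start + c.batch_size]
            Xb, yb, mb = train.X[idx], y_train[idx], train.mask[idx]
            model.zero_grad()
            pred = model.forward(Xb, mb, train=True, rng=rng)
            loss = mse(pred, yb)
            if not np.isfinite(loss):
                raise ValidationError(
                    f"NaN/Inf training loss (lr={c.lr}, batch at {start})"
                )
            dpred = 2.0 * (pred - yb) / pred.size
            model.backward(dpred)
            opt.step()
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / train.n_examples)
        if val is not None and val.n_examples:
            vpred = model.forward(val.X, val.mask, train=False, rng=None)
            vloss = mse(vpred, y_val)
            history["val_loss"].append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_state = model.state_dict()
    if val is not None and val.n_examples and c.epochs > 0:
        model.load_state_dict(best_state)
    return history


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot <= 0:
        raise ValidationError("R^2 undefined for constant y_true")
    return float(1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot)


def evaluate(
    model: _EstimatorBase,
    trials: list[SupervisedDataset],
    signal_mode: str = "fusion",
) -> EvalReport:
    """Pooled-per-trial R²: predictions and targets of each trial are
    flattened and scored together; trials are summarised as
    highest / lowest / mean.  A per-axis breakdown (mean over trials of each
    target axis's R²) is attached as supplementary detail."""
    if not trials:
        raise ValidationError("need at least one trial")
    scores: list[float] = []
    axis_scores: list[list[float]] = []
    for i, trial in enumerate(trials):
        if trial.n_examples == 0:
            warnings.warn(f"trial {i} is empty; skipped")
            continue
        pred = model.predict(trial.X, trial.mask)
        scores.append(r2_score(trial.y, pred))
        axis_scores.append(
            [
                r2_score(trial.y[:, :, a], pred[:, :, a])
                for a in range(trial.y.shape[2])
            ]
        )
    if not scores:
        raise ValidationError("all trials empty")
    per_axis = [float(v) for v in np.mean(axis_scores, axis=0)]
    return EvalReport.from_scores(scores, model.name, signal_mode, per_axis)


def grid_search(
    train: SupervisedDataset,
    val: SupervisedDataset,
    base: TransformerConfig,
    grid: dict[str, list] | None = None,
) -> tuple[TransformerConfig, list[dict]]:
    """Exhaustive sweep over hyperparameter values, selecting by val R².

    The default axes mirror the sweep the estimator was designed under:
    heads in {8, 4, 2, 1} and encoder layers in {1, 2, 5}.  Returns the best
    configuration and one record per candidate.
    """
    grid = grid or {"n_heads": [8, 4, 2, 1], "n_layers": [1, 2, 5]}
    records: list[dict] = []
    best_cfg, best_r2 = base, -np.inf
    keys = list(grid)

    def product(i: int, current: dict):
        nonlocal best_cfg, best_r2
        if i == len(keys):
            cfg = replace(base, **current)
            model = TransformerEstimator(cfg)
            train_estimator(model, train, val)
            score = r2_score(val.y, model.predict(val.X, val.mask))
            records.append({**current, "val_r2": score})
            if score > best_r2:
                best_r2, best_cfg = score, cfg
            return
        for value in grid[keys[i]]:
            product(i + 1, {**current, keys[i]: value})

    product(0, {})
    return best_cfg, records
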