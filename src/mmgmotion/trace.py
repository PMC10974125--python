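"""Signal containers.

Every stage of the pipeline exchanges :class:`SignalTrace` objects: uniformly
sampled multi-channel time series stored channel-major (``n_channels x
n_samples``) in double precision.  A :class:`Recording` groups the three traces
of one trial — raw accelerometer axes, sEMG electrodes and the
rotational-acceleration targets — which must share one sampling rate and one
duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass
class SignalTrace:
    """Uniformly sampled multi-channel real-valued time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Channel-major sample matrix; coerced to float64.
    rate_hz : float
        Sampling rate in samples/second; must be positive.
    channel_names : list of str
        One unique name per channel.
    units : list of str, optional
        Physical unit per channel (e.g. ``"m/s^2"``, ``"mV"``).  Defaults to
        ``"a.u."`` for every channel.
    """

    samples: np.ndarray
    rate_hz: float
    channel_names: list[str]
    units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channel-major matrix")
        n_channels, n_samples = self.samples.shape
        if n_channels < 1:
            raise ValidationError("trace must have at least one channel")
        if n_samples < 1:
            raise ValidationError("trace must have at least one sample")
        if not np.isfinite(self.rate_hz) or self.rate_hz <= 0:
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz!r}")
        self.rate_hz = float(self.rate_hz)
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {n_channels} channels"
            )
        if len(set(self.channel_names)) != n_channels:
            raise ValidationError("channel_names must be unique")
        if not self.units:
            self.units = ["a.u."] * n_channels
        if len(self.units) != n_channels:
            raise ValidationError("units must have one entry per channel")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        """Return the 1-D sample vector of the named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.samples[idx]

    def select(self, names: list[str]) -> "SignalTrace":
        """Sub-trace containing ``names`` in the given order."""
        idx = [self.channel_names.index(n) for n in names]
        return SignalTrace(
            self.samples[idx],
            self.rate_hz,
            [self.channel_names[i] for i in idx],
            [self.units[i] for i in idx],
        )


@dataclass
class Recording:
    """One trial: accelerometer axes, sEMG channels and kinematic targets.

    All three traces must share ``rate_hz`` and ``n_samples``; the targets are
    rotational accelerations in rad/s^2 per joint axis.
    """

    raw_accel: SignalTrace
    semg: SignalTrace
    targets: SignalTrace
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = {self.raw_accel.rate_hz, self.semg.rate_hz, self.targets.rate_hz}
        if len(rates) != 1:
            raise ValidationError(f"traces disagree on rate_hz: {sorted(rates)}")
        lengths = {
            self.raw_accel.n_samples,
            self.semg.n_samples,
            self.targets.n_samples,
        }
        if len(lengths) != 1:
            raise ValidationError(f"traces disagree on n_samples: {sorted(lengths)}")

    @property
    def rate_hz(self) -> float:
        return self.raw_accel.rate_hz

    @property
    def n_samples(self) -> int:
        return self.raw_accel.n_samples
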