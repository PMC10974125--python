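"""Six-stage biosignal conditioning applied to extracted MMG and raw sEMG.

After MMG extraction (stage 1, module :mod:`mmgmotion.extraction`) both
signal kinds pass through: DC-offset removal, 10-450 Hz zero-phase
Butterworth bandpass, full-wave rectification, linear-envelope extraction
(zero-phase low-pass of the rectified signal) and normalisation.  All stages
preserve length and are deterministic; forward-backward filtering keeps the
envelope aligned with the underlying activation (no phase lag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .trace import ValidationError


@dataclass
class PreprocessConfig:
    band_low_hz: float = 10.0
    band_high_hz: float = 450.0
    filter_order: int = 4
    envelope_cutoff_hz: float = 5.0
    normalization: str = "minmax_01"  # {minmax_01, zscore}

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValidationError("need 0 < band_low_hz < band_high_hz")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValidationError("filter_order must be a positive even integer")
        if not (0 < self.envelope_cutoff_hz < self.band_low_hz):
            raise ValidationError("envelope_cutoff_hz must lie below band_low_hz")
        if self.normalization not in ("minmax_01", "zscore"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")


def _as_signal(signal: np.ndarray) -> np.ndarray:
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValidationError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains NaN or Inf")
    return x


def remove_dc(signal: np.ndarray) -> np.ndarray:
    """Subtract the mean."""
    x = _as_signal(signal)
    return x - x.mean()


def bandpass(
    signal: np.ndarray, rate_hz: float, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (order ``filter_order``, applied
    forward-backward with second-order sections)."""
    cfg = config or PreprocessConfig()
    x = _as_signal(signal)
    nyq = rate_hz / 2
    if cfg.band_high_hz >= nyq:
        raise ValidationError(
            f"band_high_hz={cfg.band_high_hz} must be below Nyquist {nyq}"
        )
    sos = butter(
        cfg.filter_order // 2,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=rate_hz,
        output="sos",
    )
    return sosfiltfilt(sos, x)


def full_wave_rectify(signal: np.ndarray) -> np.ndarray:
    """Elementwise absolute value."""
    return np.abs(_as_signal(signal))


def linear_envelope(
    signal: np.ndarray, rate_hz: float, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Zero-phase low-pass of a rectified signal; undershoot clipped to 0."""
    cfg = config or PreprocessConfig()
    x = _as_signal(signal)
    sos = butter(4, cfg.envelope_cutoff_hz, btype="lowpass", fs=rate_hz, output="sos")
    return np.clip(sosfiltfilt(sos, x), 0.0, None)


def normalize(signal: np.ndarray, mode: str = "minmax_01") -> np.ndarray:
    """Scale to [0, 1] (``minmax_01``) or to zero mean, unit sd (``zscore``).

    A constant signal min-max normalises to all zeros (with a warning);
    z-scoring a constant signal is an error.
    """
    x = _as_signal(signal)
    if mode == "minmax_01":
        lo, hi = x.min(), x.max()
        if hi - lo <= 0:
            warnings.warn("constant signal: min-max normalization returns zeros")
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    if mode == "zscore":
        sd = x.std()
        if sd <= 0:
            raise ValidationError("cannot z-score a constant signal")
        return (x - x.mean()) / sd
    raise ValidationError(f"unknown normalization mode {mode!r}")


def preprocess_channel(
    signal: np.ndarray,
    rate_hz: float,
    config: PreprocessConfig | None = None,
    kind: str = "mmg",
) -> np.ndarray:
    """Stages 2-6 in order: DC removal, bandpass, rectification, linear
    envelope, normalisation.  ``kind`` ('mmg' or 'semg') is carried for error
    context; the stages are identical for both signal kinds."""
    if kind not in ("mmg", "semg"):
        raise ValidationError(f"kind must be 'mmg' or 'semg', got {kind!r}")
    cfg = config or PreprocessConfig()
    x = _as_signal(signal)
    if not np.any(x):
        warnings.warn(f"{kind}: constant signal: min-max normalization returns zeros")
        return np.zeros_like(x)
    stages = [
        ("remove_dc", lambda s: remove_dc(s)),
        ("bandpass", lambda s: bandpass(s, rate_hz, cfg)),
        ("full_wave_rectify", lambda s: full_wave_rectify(s)),
        ("linear_envelope", lambda s: linear_envelope(s, rate_hz, cfg)),
        ("normalize", lambda s: normalize(s, cfg.normalization)),
    ]
    for name, stage in stages:
        try:
            x = stage(x)
        except ValidationError as exc:
            raise ValidationError(f"{kind}/{name}: {exc}") from exc
    return x
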