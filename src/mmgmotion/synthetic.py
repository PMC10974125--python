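"""Synthetic multimodal recordings with known ground truth.

The generator emulates the statistical structure the extraction and
estimation stack assumes for a self-paced upper-limb exercise:

* a smooth joint oscillation at a self-chosen pace (random-phase narrowband
  motion inside ``motion_freq_hz``), whose exact discrete second difference
  is the rotational-acceleration target;
* per-muscle activation envelopes formed by half-wave-rectifying, delaying
  and low-pass filtering exercise-specific linear combinations of the joint
  accelerations — agonist/antagonist muscle pairs carry opposite signs, so
  the signed acceleration stays linearly decodable from the envelopes;
* MMG as a 10-50 Hz band-limited Gaussian carrier amplitude-modulated by the
  activation, and sEMG as a 20-450 Hz carrier modulated the same way;
* pseudo-acceleration as the low-passed (< 10 Hz) projection of the joint
  acceleration onto each sensor axis; and
* wideband white sensor noise scaled to a configured SNR.

The raw accelerometer signal is exactly ``pseudo + MMG + noise``, so every
pipeline stage can be scored against construction-time ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .trace import Recording, SignalTrace, ValidationError

MUSCLES = ("biceps_brachii", "anterior_deltoid", "middle_deltoid", "posterior_deltoid")

#: Each exercise is driven by two latent oscillations (the primary joint
#: excursion and a smaller secondary sway — single-joint exercises have few
#: effective degrees of freedom).  ``axes`` maps latents to the three joint
#: axes; ``muscles`` maps latent accelerations to the four muscle drives,
#: with agonist/antagonist pairs carrying opposite signs so that each signed
#: latent is recoverable from the rectified activations.
_EXERCISES = {
    "bicep_curl": {
        "axes": np.array([[1.0, 0.1], [0.6, 0.8], [0.2, 1.0]]),
        "muscles": np.array([[1.0, 0.15], [-1.0, 0.15], [0.15, 1.0], [0.15, -1.0]]),
    },
    "lateral_raise": {
        "axes": np.array([[0.3, 1.0], [1.0, 0.2], [0.7, 0.6]]),
        "muscles": np.array([[0.2, 1.0], [0.2, -1.0], [1.0, 0.2], [-1.0, 0.2]]),
    },
    "frontal_raise": {
        "axes": np.array([[0.8, 0.5], [0.2, 1.0], [1.0, 0.1]]),
        "muscles": np.array([[1.0, -0.2], [-1.0, -0.2], [-0.2, 1.0], [-0.2, -1.0]]),
    },
}


@dataclass
class SyntheticConfig:
    exercise: str = "bicep_curl"
    duration_s: float = 60.0
    rate_hz: float = 1000.0
    motion_freq_hz: tuple[float, float] = (0.3, 0.7)
    mmg_band_hz: tuple[float, float] = (10.0, 50.0)
    semg_band_hz: tuple[float, float] = (20.0, 450.0)
    pseudo_accel_cutoff_hz: float = 5.0
    snr_db: float = 15.0
    activation_delay_ms: float = 50.0
    #: tonic co-contraction floor: muscles keep a resting activation level,
    #: so every MMG channel stays persistently (if weakly) active
    activation_tonic: float = 0.15
    n_sensors: int = 4
    #: MMG amplitude relative to the pseudo-acceleration RMS on the dominant axis
    mmg_rel_amplitude: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exercise not in _EXERCISES:
            raise ValidationError(
                f"unknown exercise {self.exercise!r}; "
                f"expected one of {sorted(_EXERCISES)}"
            )
        if self.duration_s < 2:
            raise ValidationError("duration_s must be >= 2 s")
        nyq = self.rate_hz / 2
        for lo, hi in (self.mmg_band_hz, self.semg_band_hz):
            if not (0 < lo < hi < nyq):
                raise ValidationError("bands must lie within (0, rate/2)")
        if self.activation_delay_ms < 0:
            raise ValidationError("activation_delay_ms must be >= 0")
        if not (1 <= self.n_sensors <= len(MUSCLES)):
            raise ValidationError(f"n_sensors must be in [1, {len(MUSCLES)}]")


@dataclass
class SyntheticRecording:
    """A generated trial plus its construction-time ground truth."""

    recording: Recording
    true_mmg: np.ndarray  # (n_sensors, n) dominant-axis MMG
    true_pseudo: np.ndarray  # (n_sensors, n) dominant-axis pseudo-acceleration
    activation: np.ndarray  # (n_sensors, n), in [0, 1]
    noise: np.ndarray  # (n_sensors * 3, n) injected accelerometer noise


def _lowpass(x: np.ndarray, cutoff_hz: float, rate_hz: float, order: int = 4):
    sos = butter(order, cutoff_hz, btype="lowpass", fs=rate_hz, output="sos")
    return sosfiltfilt(sos, x, axis=-1)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, band: tuple[float, float], rate_hz: float
) -> np.ndarray:
    """Unit-variance Gaussian carrier band-limited by a zero-phase filter."""
    sos = butter(4, band, btype="bandpass", fs=rate_hz, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_motion(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one trial's kinematics and muscle activations.

    Returns ``(joint_accel (3, n), activation (n_sensors, n), angle (3, n))``.
    The joint angle per axis is a random-phase narrowband oscillation inside
    ``motion_freq_hz`` with smoothly varying amplitude; the acceleration is
    its exact discrete second difference scaled by rate² (endpoints
    replicated).  Activations are half-wave-rectified, delayed, low-passed
    linear mixes of the accelerations, normalised into [0, 1].
    """
    n = int(round(config.duration_s * config.rate_hz))
    t = np.arange(n) / config.rate_hz
    lo, hi = config.motion_freq_hz
    ex = _EXERCISES[config.exercise]
    # two latent oscillations: primary excursion plus a smaller secondary sway
    latent_angle = np.zeros((2, n))
    for j, scale in enumerate((1.0, 0.4)):
        for _ in range(3):
            f = rng.uniform(lo, hi)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.3, 1.0) * scale
            latent_angle[j] += amp * np.sin(2 * np.pi * f * t + phase)

    def second_difference(x: np.ndarray) -> np.ndarray:
        acc = np.empty_like(x)
        acc[:, 1:-1] = (x[:, 2:] - 2 * x[:, 1:-1] + x[:, :-2]) * (config.rate_hz**2)
        acc[:, 0] = acc[:, 1]
        acc[:, -1] = acc[:, -2]
        return acc

    latent_accel = second_difference(latent_angle)
    accel = ex["axes"] @ latent_accel  # (3, n) joint rotational acceleration

    delay = int(round(config.activation_delay_ms * config.rate_hz / 1000.0))
    mix = ex["muscles"][: config.n_sensors]
    drive = np.maximum(mix @ latent_accel, 0.0)  # half-wave rectified drive
    if delay:
        drive = np.concatenate([np.zeros((drive.shape[0], delay)), drive], axis=1)[
            :, :n
        ]
    act = _lowpass(drive, 3.0, config.rate_hz)
    act = np.clip(act, 0.0, None)
    peak = act.max(axis=1, keepdims=True)
    peak[peak <= 0] = 1.0
    act = config.activation_tonic + (1.0 - config.activation_tonic) * act / peak
    angle = ex["axes"] @ latent_angle
    return accel, act, angle


def synth_mmg(
    activation: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited (10-50 Hz) carrier amplitude-modulated by activation."""
    carrier = _bandlimited_noise(
        rng, activation.size, config.mmg_band_hz, config.rate_hz
    )
    return activation * carrier


def synth_semg(
    activation: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Wideband (20-450 Hz) carrier amplitude-modulated by activation."""
    carrier = _bandlimited_noise(
        rng, activation.size, config.semg_band_hz, config.rate_hz
    )
    return activation * carrier


def assemble_recording(config: SyntheticConfig) -> SyntheticRecording:
    """Generate one seeded trial.

    Per sensor, the dominant accelerometer axis carries the low-passed
    pseudo-acceleration projection plus the activation-modulated MMG; the two
    other axes carry attenuated copies of the pseudo-acceleration.  White
    noise is added to every axis, scaled so the trace-wide signal-to-noise
    ratio equals ``snr_db`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    accel, act, _ = simulate_motion(config, rng)
    n = accel.shape[1]
    ns = config.n_sensors

    pseudo_joint = _lowpass(accel, config.pseudo_accel_cutoff_hz, config.rate_hz)
    # per-sensor projection of joint motion onto the sensor's dominant axis
    proj = rng.uniform(0.5, 1.0, size=(ns, 3)) * np.sign(
        rng.uniform(-1, 1, size=(ns, 3))
    )
    axis_atten = np.array([1.0, 0.35, 0.2])  # dominant, secondary, tertiary axes

    true_pseudo = np.array([proj[s] @ pseudo_joint for s in range(ns)])
    # one vibration scale for all sensors: muscle-vibration amplitude is a
    # property of the contraction, not of how limb motion projects onto the
    # individual sensor axis
    p_rms = float(np.sqrt(np.mean(true_pseudo**2)))
    if p_rms <= 0:
        p_rms = 1.0
    true_mmg = np.empty((ns, n))
    semg = np.empty((ns, n))
    raw = np.empty((ns * 3, n))
    clean = np.empty((ns * 3, n))
    for s in range(ns):
        p = true_pseudo[s]
        m = synth_mmg(act[s], config, rng) * config.mmg_rel_amplitude * p_rms
        semg[s] = synth_semg(act[s], config, rng)
        true_mmg[s] = m
        for a, att in enumerate(axis_atten):
            clean[3 * s + a] = att * p + (m if a == 0 else 0.0)

    noise = rng.standard_normal(clean.shape)
    sig_power = np.mean(clean**2)
    target_noise_power = sig_power / 10 ** (config.snr_db / 10)
    noise *= np.sqrt(target_noise_power / np.mean(noise**2))
    raw = clean + noise

    accel_names = [
        f"sensor{s}_a{ax}" for s in range(ns) for ax in ("x", "y", "z")
    ]
    rec = Recording(
        raw_accel=SignalTrace(
            raw, config.rate_hz, accel_names, ["m/s^2"] * ns * 3
        ),
        semg=SignalTrace(
            semg,
            config.rate_hz,
            [f"semg_{MUSCLES[s]}" for s in range(ns)],
            ["mV"] * ns,
        ),
        targets=SignalTrace(
            accel, config.rate_hz, ["joint_ax", "joint_ay", "joint_az"],
            ["rad/s^2"] * 3,
        ),
        meta={"exercise": config.exercise, "seed": config.seed},
    )
    return SyntheticRecording(
        recording=rec,
        true_mmg=true_mmg,
        true_pseudo=true_pseudo,
        activation=act,
        noise=noise,
    )


def default_fixture(
    n_trials: int = 5,
    exercises: tuple[str, ...] = ("bicep_curl", "lateral_raise", "frontal_raise"),
    base_seed: int = 0,
    **overrides,
) -> list[SyntheticRecording]:
    """The study fixture: ``n_trials`` seeded trials per exercise."""
    out = []
    for e_idx, exercise in enumerate(exercises):
        for trial in range(n_trials):
            seed = (base_seed + 1000 * e_idx + trial) % (2**31 - 1)
            cfg = SyntheticConfig(exercise=exercise, seed=seed, **overrides)
            out.append(assemble_recording(cfg))
    return out
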