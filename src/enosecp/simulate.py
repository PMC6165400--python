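"""Synthetic metal-oxide (MOS) gas-sensor array response generator.

Emulates the record structure of a headspace-injection e-nose experiment:
each sample is a multichannel voltage time series with a clean-air baseline
phase, a gas injection, a first-order rise toward a class- and sensor-specific
steady-state amplitude, and an exponential decline back toward baseline once
clean carrier gas is pumped in again.  Additive Gaussian noise, a per-sample
linear baseline drift and per-sample amplitude jitter provide the within-class
variability; class identity is carried by the amplitude pattern across the
sensor panel.

Samples drawn this way are i.i.d. within a class and classes are sampled in a
fixed balanced layout, so a pooled labelled dataset is exchangeable -- the
assumption under which conformal-prediction validity is tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ClassProfileSet",
    "SimulationConfig",
    "SensorRecord",
    "make_class_profiles",
    "simulate_sample",
    "simulate_dataset",
    "iter_dataset",
]

# Reference record length (seconds) of the full-resolution protocol: 20 s
# baseline + 180 s rise/stabilize + 140 s decline.  Kinetic time constants of
# generated profiles are expressed relative to this span so that short test
# records keep the same curve shapes.
_REFERENCE_DURATION = 340.0


@dataclass(frozen=True)
class ClassProfileSet:
    """Per-class steady-state response amplitudes plus per-sensor kinetics.

    Attributes
    ----------
    amplitudes : ndarray of shape (n_classes, n_sensors)
        Steady-state response magnitude of each sensor to each class, volts.
    rise_tau, decay_tau : ndarray of shape (n_sensors,)
        First-order rise / exponential-decay time constants, seconds.
    """

    amplitudes: np.ndarray
    rise_tau: np.ndarray
    decay_tau: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        rise = np.asarray(self.rise_tau, dtype=float)
        decay = np.asarray(self.decay_tau, dtype=float)
        if amp.ndim != 2:
            raise ValueError("amplitudes must be a (n_classes, n_sensors) array")
        if amp.shape[0] < 2:
            raise ValueError("need at least 2 classes")
        if amp.shape[1] < 1:
            raise ValueError("need at least 1 sensor")
        if not np.all(np.isfinite(amp)) or np.any(amp < 0):
            raise ValueError("amplitudes must be finite and non-negative")
        if rise.shape != (amp.shape[1],) or decay.shape != (amp.shape[1],):
            raise ValueError("time-constant vectors must have one entry per sensor")
        if np.any(rise <= 0) or np.any(decay <= 0):
            raise ValueError("time constants must be positive")
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "rise_tau", rise)
        object.__setattr__(self, "decay_tau", decay)

    @property
    def n_classes(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.amplitudes.shape[1]


@dataclass(frozen=True)
class SimulationConfig:
    """Timing and noise parameters of one simulated acquisition.

    Defaults are the scaled test-suite resolution (10 Hz, 34 s records with
    the same 20/180/140 phase proportions as the full protocol); use
    :meth:`full_scale` for the full-resolution 100 Hz / 340 s records.
    """

    sampling_rate: float = 10.0          # Hz
    baseline_duration: float = 2.0       # s of clean air before injection
    rise_duration: float = 18.0          # s of reaction / stabilization
    decline_duration: float = 14.0       # s of clean-air recovery
    noise_sd: float = 0.01               # volts, i.i.d. per time point
    drift_slope_sd: float = 1e-4         # volts/s, one slope per sensor per sample
    amplitude_jitter_sd: float = 0.05    # volts, per sensor per sample
    baseline_level: float = 0.5          # volts, clean-air output
    samples_per_class: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("baseline_duration", "rise_duration", "decline_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sd", "drift_slope_sd", "amplitude_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")

    @classmethod
    def full_scale(cls, **overrides) -> "SimulationConfig":
        """Full-resolution protocol: 100 Hz, 20 s + 180 s + 140 s = 340 s."""
        base = dict(
            sampling_rate=100.0,
            baseline_duration=20.0,
            rise_duration=180.0,
            decline_duration=140.0,
            samples_per_class=50,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + self.rise_duration + self.decline_duration

    @property
    def n_timepoints(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    @property
    def injection_index(self) -> int:
        """0-based index of the first post-injection sample."""
        return int(round(self.baseline_duration * self.sampling_rate))

    @property
    def timescale(self) -> float:
        """Record span relative to the full 340 s protocol."""
        return self.total_duration / _REFERENCE_DURATION


@dataclass
class SensorRecord:
    """One sample's raw multichannel voltage trace.

    ``values`` has shape (n_sensors, n_timepoints); time of sample k is
    ``k / sampling_rate`` with k = 0 at the start of the baseline phase.
    """

    values: np.ndarray
    sampling_rate: float
    injection_index: int
    label: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a (n_sensors, n_timepoints) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if not 0 < self.injection_index < v.shape[1]:
            raise ValueError("injection_index must lie strictly inside the record")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.values = v

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) / self.sampling_rate


def make_class_profiles(
    n_classes: int,
    n_sensors: int,
    separation: float = 1.0,
    seed: int = 0,
    *,
    timescale: float = 1.0,
) -> ClassProfileSet:
    """Draw a random, reproducible panel of class response profiles.

    Each sensor gets a base amplitude in [0.8, 2.5] V; class c's amplitude on
    sensor s is ``base_s * exp(separation * delta_cs)`` with delta ~ N(0, 0.4).
    ``separation = 0`` therefore makes every class identical, and for a fixed
    seed the expected between-class amplitude distance grows monotonically
    with ``separation``.  Amplitudes are positive by construction.

    ``timescale`` rescales the kinetic time constants (drawn for the full
    340 s protocol) to shorter records.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_sensors < 1:
        raise ValueError("n_sensors must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if timescale <= 0:
        raise ValueError("timescale must be positive")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.8, 2.5, size=n_sensors)
    delta = rng.normal(0.0, 0.4, size=(n_classes, n_sensors))
    amplitudes = base * np.exp(separation * delta)
    rise_tau = rng.uniform(20.0, 60.0, size=n_sensors) * timescale
    decay_tau = rng.uniform(40.0, 120.0, size=n_sensors) * timescale
    return ClassProfileSet(amplitudes, rise_tau, decay_tau)


def simulate_sample(
    profiles: ClassProfileSet,
    class_id: int,
    config: SimulationConfig,
    seed,
) -> SensorRecord:
    """Simulate one acquisition of a sample from ``class_id`` (1-based).

    Per sensor the trace is ``baseline_level + drift*t + response + noise``
    where the response is 0 before injection, a first-order rise
    ``A * (1 - exp(-(t - t_inj)/rise_tau))`` during the reaction phase, and an
    exponential decay of the rise-end value toward baseline afterwards.
    Deterministic given ``seed``.
    """
    if not 1 <= int(class_id) <= profiles.n_classes:
        raise ValueError(
            f"class_id {class_id} outside 1..{profiles.n_classes}"
        )
    rng = np.random.default_rng(seed)
    n_sensors = profiles.n_sensors
    n = config.n_timepoints
    t = np.arange(n) / config.sampling_rate

    amp = profiles.amplitudes[int(class_id) - 1] + rng.normal(
        0.0, config.amplitude_jitter_sd, size=n_sensors
    )
    drift = rng.normal(0.0, config.drift_slope_sd, size=n_sensors)
    noise = rng.normal(0.0, config.noise_sd, size=(n_sensors, n))

    t_inj = config.baseline_duration
    t_dec = config.baseline_duration + config.rise_duration
    rise_mask = (t >= t_inj) & (t < t_dec)
    dec_mask = t >= t_dec

    response = np.zeros((n_sensors, n))
    rise_t = t[rise_mask] - t_inj
    response[:, rise_mask] = amp[:, None] * (
        1.0 - np.exp(-rise_t[None, :] / profiles.rise_tau[:, None])
    )
    rise_end = amp * (1.0 - np.exp(-config.rise_duration / profiles.rise_tau))
    dec_t = t[dec_mask] - t_dec
    response[:, dec_mask] = rise_end[:, None] * np.exp(
        -dec_t[None, :] / profiles.decay_tau[:, None]
    )

    values = config.baseline_level + drift[:, None] * t[None, :] + response + noise
    return SensorRecord(
        values=values,
        sampling_rate=config.sampling_rate,
        injection_index=config.injection_index,
        label=int(class_id),
    )


def iter_dataset(
    profiles: ClassProfileSet, config: SimulationConfig
) -> Iterator[SensorRecord]:
    """Yield the balanced dataset one record at a time (memory-light).

    Record i (class-major order) gets an independent seed derived from
    ``SeedSequence([config.seed, i])``, so the dataset is reproducible and
    any record can be regenerated without generating the preceding ones.
    """
    i = 0
    for class_id in range(1, profiles.n_classes + 1):
        for _ in range(config.samples_per_class):
            yield simulate_sample(
                profiles, class_id, config, np.random.SeedSequence([config.seed, i])
            )
            i += 1


def simulate_dataset(
    profiles: ClassProfileSet, config: SimulationConfig
) -> list[SensorRecord]:
    """Materialized balanced dataset: n_classes * samples_per_class records."""
    return list(iter_dataset(profiles, config))
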