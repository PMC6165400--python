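"""Baseline calibration and transient-response feature extraction.

Raw sensor voltages are first calibrated by subtracting the clean-air
baseline, V = Vs - V0, with V0 estimated per sensor as the mean over the
pre-injection window.  Eight scalar features are then extracted per sensor:

1. Vmax = max |V| over the record,
2. Vint = trapezoidal integral of V over the record (volt-seconds),
3.-8. min and max of the exponential moving average (EMA) of the first
   difference of V, at three smoothing factors a = 1/(100*SR), 1/(10*SR),
   1/SR where SR is the sampling rate (Hz).  The EMA recurrence, with 1-based
   sample index k, is

       y(1) = a * V(1)
       y(k) = (1 - a) * y(k-1) + a * (V(k) - V(k-1)),

   and the min/max are taken over the post-injection index window with
   strict bounds (k_lo < k < k_hi); at full resolution (100 Hz, 340 s) the
   default window is 2000 < k < 34000.

A 16-sensor record therefore yields 8 * 16 = 128 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "FeatureConfig",
    "CalibratedRecord",
    "FeatureMatrix",
    "subtract_baseline",
    "max_feature",
    "integral_feature",
    "ema_filter",
    "ema_features",
    "extract_features",
    "build_feature_matrix",
    "default_smoothing_factors",
]

_TOL = 1e-9


def default_smoothing_factors(sampling_rate: float) -> tuple[float, float, float]:
    """EMA smoothing factors a = 1/(100*SR), 1/(10*SR), 1/SR."""
    return (
        1.0 / (100.0 * sampling_rate),
        1.0 / (10.0 * sampling_rate),
        1.0 / sampling_rate,
    )


@dataclass(frozen=True)
class FeatureConfig:
    """Windows and smoothing factors for feature extraction.

    ``None`` fields are resolved per record: baseline window = pre-injection
    span, integration window = whole record, EMA index window =
    (injection_index, n_timepoints) as strict 1-based bounds, smoothing
    factors = :func:`default_smoothing_factors` at the record's rate.
    """

    baseline_window: tuple[float, float] | None = None   # seconds, half-open
    integration_window: tuple[float, float] | None = None  # seconds, closed
    ema_window: tuple[int, int] | None = None            # strict 1-based bounds
    smoothing_factors: tuple[float, ...] | None = None
    integration_rule: str = "trapezoid"

    def __post_init__(self) -> None:
        for name in ("baseline_window", "integration_window", "ema_window"):
            w = getattr(self, name)
            if w is not None:
                if len(w) != 2 or not w[0] < w[1]:
                    raise ValueError(f"{name} must be an increasing pair")
        if self.smoothing_factors is not None:
            for a in self.smoothing_factors:
                if not 0.0 < a <= 1.0:
                    raise ValueError("smoothing factors must lie in (0, 1]")
        if self.integration_rule != "trapezoid":
            raise ValueError(f"unknown integration rule {self.integration_rule!r}")


@dataclass
class CalibratedRecord:
    """Baseline-subtracted voltages, same shape as the source record."""

    values: np.ndarray
    sampling_rate: float
    injection_index: int
    label: int | None = None

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) / self.sampling_rate


@dataclass
class FeatureMatrix:
    """Samples x features matrix with named columns and per-sample labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        if v.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        labels = np.asarray(self.labels)
        if labels.shape != (v.shape[0],):
            raise ValueError("labels must have one entry per row")
        self.values = v
        self.labels = labels

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_arrays(cls, values, labels) -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        names = [f"f{j:03d}" for j in range(values.shape[1])]
        return cls(values, names, np.asarray(labels))


def subtract_baseline(record, config: FeatureConfig | None = None) -> CalibratedRecord:
    """Calibrate a record: V = Vs - V0, V0 = per-sensor pre-injection mean.

    The baseline window defaults to [0, injection time); it must precede the
    injection and contain at least one sample.
    """
    config = config or FeatureConfig()
    sr = record.sampling_rate
    inj_time = record.injection_index / sr
    w0, w1 = config.baseline_window or (0.0, inj_time)
    if w1 > inj_time + _TOL:
        raise ValueError(
            f"baseline window ({w0}, {w1}) extends past injection at {inj_time} s"
        )
    t = np.arange(record.values.shape[1]) / sr
    mask = (t >= w0 - _TOL) & (t < w1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    v0 = record.values[:, mask].mean(axis=1)
    return CalibratedRecord(
        values=record.values - v0[:, None],
        sampling_rate=sr,
        injection_index=record.injection_index,
        label=record.label,
    )


def max_feature(signal) -> float:
    """Vmax = max(|V|) over the full trace."""
    v = np.asarray(signal, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    return float(np.max(np.abs(v)))


def integral_feature(
    signal, sampling_rate: float, window: tuple[float, float] | None = None
) -> float:
    """Vint: trapezoidal integral of V(t) dt over ``window`` (volt-seconds).

    Exact for piecewise-linear signals on the sample grid.  ``window`` is a
    closed time interval defaulting to the whole trace; a window extending
    beyond the trace is an error.
    """
    v = np.asarray(signal, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples to integrate")
    t = np.arange(v.size) / sampling_rate
    if window is None:
        seg = v
        ts = t
    else:
        w0, w1 = window
        if w0 < -_TOL or w1 > t[-1] + _TOL:
            raise ValueError(f"integration window ({w0}, {w1}) outside trace span")
        mask = (t >= w0 - _TOL) & (t <= w1 + _TOL)
        seg = v[mask]
        ts = t[mask]
        if seg.size < 2:
            raise ValueError("integration window contains fewer than 2 samples")
    return float(np.trapezoid(seg, ts))


def ema_filter(signal, a: float) -> np.ndarray:
    """Full EMA-of-first-difference trace y(k) (0-based array, k = index + 1).

    Implements y(1) = a*V(1), y(k) = (1-a)*y(k-1) + a*(V(k) - V(k-1)) via a
    linear IIR filter over the first difference (with V(0) := 0 so that the
    first difference at k=1 equals V(1)).
    """
    if not 0.0 < a <= 1.0:
        raise ValueError("smoothing factor a must lie in (0, 1]")
    v = np.asarray(signal, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    dv = np.diff(v, prepend=0.0)
    return lfilter([a], [1.0, -(1.0 - a)], dv)


def ema_features(
    signal, a: float, window: tuple[int, int] | None = None
) -> tuple[float, float]:
    """(min, max) of the EMA trace restricted to a strict 1-based index window.

    ``window = (k_lo, k_hi)`` keeps samples with k_lo < k < k_hi; the default
    (1, n+1) keeps every k >= 2, i.e. the whole trace after the first sample.
    """
    y = ema_filter(signal, a)
    n = y.size
    k_lo, k_hi = window if window is not None else (1, n + 1)
    if not (1 <= k_lo and k_hi <= n + 1 and k_hi - k_lo >= 2):
        raise ValueError(
            f"EMA window ({k_lo}, {k_hi}) invalid for trace of length {n}"
        )
    seg = y[k_lo : k_hi - 1]  # 1-based k in (k_lo, k_hi)
    return float(seg.min()), float(seg.max())


def _sensor_feature_names(n_sensors: int, n_factors: int) -> list[str]:
    names = []
    for s in range(1, n_sensors + 1):
        names.append(f"s{s:02d}_max")
        names.append(f"s{s:02d}_int")
        for j in range(1, n_factors + 1):
            names.append(f"s{s:02d}_ema{j}_min")
            names.append(f"s{s:02d}_ema{j}_max")
    return names


def extract_features(record, config: FeatureConfig | None = None):
    """Per-sensor [Vmax, Vint, (min,max) EMA at each smoothing factor].

    Returns ``(vector, names)`` where the vector has 8 * n_sensors entries
    for the default three smoothing factors (ordered ascending).
    """
    config = config or FeatureConfig()
    cal = subtract_baseline(record, config)
    sr = cal.sampling_rate
    factors = config.smoothing_factors or default_smoothing_factors(sr)
    factors = tuple(sorted(factors))
    window = config.ema_window or (cal.injection_index, cal.n_timepoints)
    out: list[float] = []
    for s in range(cal.n_sensors):
        v = cal.values[s]
        out.append(max_feature(v))
        out.append(integral_feature(v, sr, config.integration_window))
        for a in factors:
            mn, mx = ema_features(v, a, window)
            out.extend((mn, mx))
    names = _sensor_feature_names(cal.n_sensors, len(factors))
    return np.asarray(out), names


def build_feature_matrix(
    records: Iterable, config: FeatureConfig | None = None
) -> FeatureMatrix:
    """Stack per-record feature vectors into a FeatureMatrix (row = record).

    Accepts any iterable of records (a generator keeps memory at one record);
    all records must share sensor count and sampling rate.
    """
    config = config or FeatureConfig()
    rows: list[np.ndarray] = []
    labels: list = []
    names: list[str] | None = None
    shape_key = None
    for rec in records:
        key = (rec.values.shape[0], rec.sampling_rate)
        if shape_key is None:
            shape_key = key
        elif key != shape_key:
            raise ValueError(
                f"heterogeneous records: {key} vs {shape_key} (sensors, rate)"
            )
        vec, names = extract_features(rec, config)
        rows.append(vec)
        labels.append(rec.label)
    if not rows:
        raise ValueError("no records supplied")
    return FeatureMatrix(np.vstack(rows), names, np.asarray(labels))
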