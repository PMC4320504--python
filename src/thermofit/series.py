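"""Core containers shared across the pipeline.

All model dynamics run in *deviation coordinates*: the recovery trace is
expressed as a deviation from the post-exercise temperature ``y0``, so the
deviation series starts at 0 and the controller's reference becomes
``r = T - y0`` (basal minus post-exercise temperature).  Absolute
temperatures (degrees C) appear only at the I/O boundary.

Time is measured in **sample units** throughout (1 sample = 10 s at the
0.1 Hz acquisition rate); all rate parameters are therefore per-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "InvalidParameterError",
    "ModelParams",
    "TimeGrid",
    "DeviationSeries",
    "TemperatureSeries",
    "ControlState",
    "Protocol",
    "ReferenceSignal",
    "ROI_LABELS",
]


class InvalidParameterError(ValueError):
    """A model or protocol parameter is non-finite or out of its domain."""


#: The 14 hand-dorsum regions of interest: metacarpophalangeal joints of all
#: five fingers, the thumb interphalangeal joint, and proximal/distal
#: interphalangeal joints of fingers II-V.  Indexed 1..14.
ROI_LABELS: tuple[str, ...] = (
    "I MCP",
    "thumb IP",
    "II MCP",
    "II IPP",
    "II IPD",
    "III MCP",
    "III IPP",
    "III IPD",
    "IV MCP",
    "IV IPP",
    "IV IPD",
    "V MCP",
    "V IPP",
    "V IPD",
)


@dataclass(frozen=True)
class ModelParams:
    """The four functional parameters of one thermoregulatory response.

    Attributes
    ----------
    lag_time : float
        LT, delay (samples) between end of exercise and onset of active
        re-warming; the supervisor's open->closed loop switch time.
    pole : float
        a, open-loop plant pole (1/sample); inverse of the plant time
        constant.  The plant input gain equals the pole (unitary-gain
        plant), so it is not stored separately.
    disturbance : float
        d, constant passive heat-exchange input, in deviation-scale
        temperature units.  Negative values produce the post-exercise
        undershoot.
    integral_gain : float
        K, integral controller gain (1/sample); strength of the active
        vasodilatory recovery.
    """

    lag_time: float
    pole: float
    disturbance: float
    integral_gain: float

    def __post_init__(self) -> None:
        for name in ("lag_time", "pole", "disturbance", "integral_gain"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        """Return (LT, a, d, K) as a float array."""
        return np.array(
            [self.lag_time, self.pole, self.disturbance, self.integral_gain],
            dtype=float,
        )

    @classmethod
    def from_array(cls, x) -> "ModelParams":
        lt, a, d, k = (float(v) for v in x)
        return cls(lag_time=lt, pole=a, disturbance=d, integral_gain=k)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid. ``t0 = 0`` marks the end of the exercise."""

    n_samples: int
    dt: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise InvalidParameterError("grid needs at least 2 samples")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise InvalidParameterError(f"dt must be positive, got {self.dt!r}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.n_samples - 1)


def _check_values(grid: TimeGrid, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != grid.n_samples:
        raise ValueError(
            f"values length {arr.size} does not match grid ({grid.n_samples})"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("series values must be finite")
    return arr


@dataclass(frozen=True)
class DeviationSeries:
    """Temperature deviation from the post-exercise value on a grid."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_values(self.grid, self.values))


@dataclass(frozen=True)
class TemperatureSeries:
    """One ROI's absolute-temperature trace with recording metadata."""

    grid: TimeGrid
    values: np.ndarray
    roi_label: str = ""
    subject_id: str = ""
    group_label: str = "unknown"  # "PsA" | "HC" | "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_values(self.grid, self.values))

    def with_values(self, values) -> "TemperatureSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class ControlState:
    """Plant/controller state at a regime boundary."""

    y: float
    m: float
    regime: str = "closed_loop"  # "open_loop" | "closed_loop"

    def __post_init__(self) -> None:
        if self.regime not in ("open_loop", "closed_loop"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not (np.isfinite(self.y) and np.isfinite(self.m)):
            raise InvalidParameterError("control state must be finite")


@dataclass(frozen=True)
class Protocol:
    """Acquisition protocol, in samples at the given sampling rate.

    Defaults encode the measurement session: 1.5 min baseline (9 samples),
    a 2 min isometric-exercise gap that is not recorded (12 samples), and
    5 min of recovery recording (30 samples), all at 0.1 Hz.
    """

    baseline_samples: int = 9
    exercise_samples: int = 12
    recovery_samples: int = 30
    sampling_rate_hz: float = 0.1

    def __post_init__(self) -> None:
        if self.baseline_samples < 0:
            raise InvalidParameterError("baseline_samples must be >= 0")
        if self.exercise_samples <= 0 or self.sampling_rate_hz <= 0:
            raise InvalidParameterError("protocol durations/rate must be positive")
        if self.recovery_samples < 2:
            raise InvalidParameterError("recovery needs at least 2 samples")

    @property
    def recorded_samples(self) -> int:
        """Samples actually present in an export (the gap is absent)."""
        return self.baseline_samples + self.recovery_samples

    @property
    def dt_seconds(self) -> float:
        return 1.0 / self.sampling_rate_hz


@dataclass(frozen=True)
class ReferenceSignal:
    """Basal temperature T, post-exercise temperature y0, reference r = T - y0."""

    T: float
    y0: float
    r: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.r is None:
            object.__setattr__(self, "r", self.T - self.y0)
        if not (np.isfinite(self.T) and np.isfinite(self.y0) and np.isfinite(self.r)):
            raise InvalidParameterError("reference signal must be finite")
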