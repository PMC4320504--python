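"""Ingestion and preprocessing of per-ROI thermal-camera exports.

A recording is a CSV with a ``time_s`` column and one column per ROI,
covering the baseline and recovery phases back to back (the exercise gap
is not recorded).  Preprocessing smooths the full trace with a centred
moving average (span 5 by default, shrinking symmetric windows at the
edges), splits it at the protocol boundary, and measures the reference
quantities: basal temperature T (baseline mean), post-exercise
temperature y0 (first recovery sample) and the deviation reference
r = T - y0.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .series import (
    DeviationSeries,
    Protocol,
    ReferenceSignal,
    ROI_LABELS,
    TemperatureSeries,
    TimeGrid,
)

__all__ = [
    "FormatError",
    "LabelingError",
    "ProtocolError",
    "read_roi_csv",
    "smooth",
    "moving_average",
    "segment_phases",
    "concat_phases",
    "compute_reference",
    "deviation_transform",
    "PLAUSIBLE_RANGE",
]

#: Physiologically plausible skin-temperature window (degrees C); samples
#: outside it are treated as sensor dropouts.
PLAUSIBLE_RANGE = (15.0, 42.0)

#: Maximum tolerated fraction of masked samples per series.
_MAX_MASKED_FRACTION = 0.10


class FormatError(ValueError):
    """The export file violates the expected CSV dialect."""


class LabelingError(KeyError):
    """A column name is not one of the 14 known ROI labels."""


class ProtocolError(ValueError):
    """Series length and protocol phase durations disagree."""


def _interpolate_masked(values: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN runs; endpoints extend the nearest value."""
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    if bad.mean() > _MAX_MASKED_FRACTION:
        raise FormatError(
            f"{bad.sum()} of {values.size} samples masked; exceeds the "
            f"{_MAX_MASKED_FRACTION:.0%} cap"
        )
    idx = np.arange(values.size)
    return np.interp(idx, idx[~bad], values[~bad])


def read_roi_csv(path, protocol: Protocol) -> list[TemperatureSeries]:
    """Read one subject's export into one series per ROI column.

    The time column must be uniformly spaced at the protocol's sampling
    rate and the row count must equal baseline + recovery samples.
    Out-of-window temperatures are masked with a warning and linearly
    interpolated (at most 10% of a series).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError("expected a time column plus at least one ROI column")
    time_col = df.columns[0]
    t = df[time_col].to_numpy(dtype=float)
    steps = np.diff(t)
    if t.size < 2 or steps.min() <= 0 or np.ptp(steps) > 1e-6 * max(1.0, steps[0]):
        raise FormatError("time column is not uniformly increasing")
    if df.shape[0] != protocol.recorded_samples:
        raise ProtocolError(
            f"{df.shape[0]} rows but protocol prescribes "
            f"{protocol.recorded_samples} (baseline + recovery)"
        )
    dt = float(steps[0])
    known = set(ROI_LABELS)
    out: list[TemperatureSeries] = []
    for col in df.columns[1:]:
        label = str(col).strip()
        if label not in known:
            raise LabelingError(f"unknown ROI column {label!r}")
        values = df[col].to_numpy(dtype=float)
        lo, hi = PLAUSIBLE_RANGE
        mask = np.isfinite(values) & ((values < lo) | (values > hi))
        if mask.any():
            if mask.mean() <= _MAX_MASKED_FRACTION:
                # isolated dropouts: mask and bridge them
                warnings.warn(
                    f"{mask.sum()} sample(s) in ROI {label!r} outside the "
                    f"[{lo}, {hi}] degC window; masked",
                    stacklevel=2,
                )
                values = np.where(mask, np.nan, values)
            else:
                # a sustained excursion is a property of the curve, not a
                # sensor fault; keep it and let fit exclusion judge it
                warnings.warn(
                    f"{mask.sum()} sample(s) in ROI {label!r} outside the "
                    f"[{lo}, {hi}] degC window; sustained excursion retained",
                    stacklevel=2,
                )
        values = _interpolate_masked(values)
        grid = TimeGrid(n_samples=values.size, dt=dt, t0=float(t[0]))
        out.append(TemperatureSeries(grid=grid, values=values, roi_label=label))
    return out


def moving_average(values: np.ndarray, span: int = 5) -> np.ndarray:
    """Centred moving average with shrinking symmetric edge windows.

    At position i the half-width is ``min((span-1)/2, i, n-1-i)``, so the
    first/last points are untouched and interior points use the full span.
    Affine signals pass through unchanged in the interior.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError(f"span must be odd and >= 1, got {span}")
    values = np.asarray(values, dtype=float)
    n = values.size
    if span > n:
        raise ValueError(f"span {span} exceeds series length {n}")
    half = (span - 1) // 2
    out = np.empty_like(values)
    csum = np.concatenate(([0.0], np.cumsum(values)))
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def smooth(series: TemperatureSeries, span: int = 5) -> TemperatureSeries:
    """Smooth a full trace (baseline and recovery jointly) with span 5."""
    return series.with_values(moving_average(series.values, span))


def segment_phases(
    series: TemperatureSeries, protocol: Protocol
) -> tuple[TemperatureSeries, TemperatureSeries]:
    """Split a recorded trace at the baseline/recovery boundary.

    The recovery grid is re-originated to t0 = 0 (end of exercise).
    """
    nb, nr = protocol.baseline_samples, protocol.recovery_samples
    if series.grid.n_samples != nb + nr:
        raise ProtocolError(
            f"series has {series.grid.n_samples} samples, protocol "
            f"prescribes {nb} + {nr}"
        )
    dt = series.grid.dt
    if nb >= 2:
        baseline = replace(
            series,
            grid=TimeGrid(n_samples=nb, dt=dt, t0=series.grid.t0),
            values=series.values[:nb],
        )
    else:
        baseline = None  # no usable baseline phase
    recovery = replace(
        series,
        grid=TimeGrid(n_samples=nr, dt=dt, t0=0.0),
        values=series.values[nb:],
    )
    return baseline, recovery


def concat_phases(
    baseline: TemperatureSeries | None, recovery: TemperatureSeries
) -> TemperatureSeries:
    """Re-join the phases; inverse of :func:`segment_phases`."""
    if baseline is None:
        return recovery
    values = np.concatenate([baseline.values, recovery.values])
    grid = TimeGrid(
        n_samples=values.size, dt=baseline.grid.dt, t0=baseline.grid.t0
    )
    return replace(baseline, grid=grid, values=values)


def compute_reference(
    baseline: TemperatureSeries | None, recovery: TemperatureSeries
) -> ReferenceSignal:
    """Measure T (baseline time-average), y0 (first recovery sample), r.

    An empty baseline cannot supply T; callers must then construct the
    :class:`ReferenceSignal` explicitly.
    """
    if baseline is None or baseline.grid.n_samples == 0:
        raise ValueError("empty baseline: supply T explicitly")
    if recovery.grid.n_samples == 0:
        raise ValueError("empty recovery phase")
    T = float(np.mean(baseline.values))
    y0 = float(recovery.values[0])
    return ReferenceSignal(T=T, y0=y0)


def deviation_transform(
    recovery: TemperatureSeries, ref: ReferenceSignal
) -> DeviationSeries:
    """Express the recovery in deviation coordinates (subtract y0)."""
    return DeviationSeries(grid=recovery.grid, values=recovery.values - ref.y0)
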