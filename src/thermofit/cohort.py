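"""Synthetic cohort generator.

Emulates the study design end to end: two groups (PsA patients and
healthy controls), 14 hand ROIs per subject, each contributing one
baseline+recovery temperature recording.  Per-(group, ROI) population
means and standard deviations of the four model parameters are shipped
with the package (``data/group_params.csv``); individual parameters are
drawn from truncated normals on the estimation search space, curves are
simulated with the switched feedback model, and iid Gaussian measurement
noise is added (default SD 0.04 degC, the camera's temperature
resolution).

The default cohort (11 PsA, 9 HC) reproduces the study's bookkeeping:
280 curves, 154 PsA and 126 HC.  Every record keeps its generating
parameters so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult, SearchSpace
from .model import simulate_response, to_absolute
from .series import (
    ModelParams,
    Protocol,
    ReferenceSignal,
    ROI_LABELS,
    TemperatureSeries,
    TimeGrid,
)

__all__ = [
    "GroupParamTable",
    "CohortRecord",
    "default_group_params",
    "draw_params",
    "generate_curve",
    "generate_cohort",
    "write_cohort",
    "cohort_truth_frame",
]

_PARAM_COLS = ("lt", "a", "d", "k")
_FIELD_BY_COL = {
    "lt": "lag_time",
    "a": "pole",
    "d": "disturbance",
    "k": "integral_gain",
}
_BOUNDS_ATTR = {"lt": "lt_bounds", "a": "a_bounds", "d": "d_bounds", "k": "k_bounds"}

#: Defaults for the per-subject reference quantities: basal temperature
#: ~N(30 degC, 1) and a positive deviation reference r ~N(0.8 degC, 0.3).
BASAL_MEAN, BASAL_SD = 30.0, 1.0
REFERENCE_MEAN, REFERENCE_SD = 0.8, 0.3

DEFAULT_NOISE_SD = 0.04


class ConfigError(KeyError):
    """A (group, ROI) entry is missing from the parameter table."""


@dataclass(frozen=True)
class GroupParamTable:
    """Population mean/SD of (LT, a, d, K) per (group, ROI)."""

    frame: pd.DataFrame
    space: SearchSpace = field(default_factory=SearchSpace)

    def __post_init__(self) -> None:
        required = {"roi_label", "group"} | {
            f"{p}_{s}" for p in _PARAM_COLS for s in ("mean", "sd")
        }
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"parameter table missing columns: {sorted(missing)}")
        for p in _PARAM_COLS:
            if (self.frame[f"{p}_sd"] < 0).any():
                raise ValueError(f"negative SD for parameter {p}")
            lo, hi = getattr(self.space, _BOUNDS_ATTR[p])
            means = self.frame[f"{p}_mean"]
            if ((means < lo) | (means > hi)).any():
                raise ValueError(f"{p} mean outside the search space")

    def row(self, group: str, roi_label: str) -> pd.Series:
        sel = self.frame[
            (self.frame["group"] == group) & (self.frame["roi_label"] == roi_label)
        ]
        if sel.empty:
            raise ConfigError(f"no entry for group={group!r}, roi={roi_label!r}")
        return sel.iloc[0]

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())


def default_group_params() -> GroupParamTable:
    """Load the packaged per-ROI population parameter table."""
    with resources.files("thermofit.data").joinpath("group_params.csv").open() as fh:
        frame = pd.read_csv(fh)
    return GroupParamTable(frame=frame)


@dataclass
class CohortRecord:
    """One subject x ROI recording with its generative ground truth."""

    subject_id: str
    group_label: str
    roi_label: str
    series: TemperatureSeries
    reference: ReferenceSignal
    true_params: ModelParams | None = None
    fit: FitResult | None = None


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Normal draw truncated to [lo, hi] by resampling (<=100 tries, then clip)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_params(
    table: GroupParamTable, group: str, roi_label: str, rng_seed
) -> ModelParams:
    """Draw one subject's (LT, a, d, K) for a (group, ROI) population."""
    rng = _as_rng(rng_seed)
    row = table.row(group, roi_label)
    draws = {}
    for p in _PARAM_COLS:
        lo, hi = getattr(table.space, _BOUNDS_ATTR[p])
        draws[_FIELD_BY_COL[p]] = _truncated_normal(
            rng, float(row[f"{p}_mean"]), float(row[f"{p}_sd"]), lo, hi
        )
    return ModelParams(**draws)


def generate_curve(
    params: ModelParams,
    ref: ReferenceSignal,
    protocol: Protocol | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng_seed=None,
    **meta,
) -> TemperatureSeries:
    """Simulate one full recording: noisy baseline at T, then the model recovery."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    protocol = protocol or Protocol()
    rng = _as_rng(rng_seed)
    nb, nr = protocol.baseline_samples, protocol.recovery_samples
    recovery_grid = TimeGrid(n_samples=nr, dt=1.0, t0=0.0)
    dev = simulate_response(params, ref.r, recovery_grid)
    recovery = to_absolute(dev, ref.y0).values
    baseline = np.full(nb, ref.T)
    values = np.concatenate([baseline, recovery])
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.size)
    grid = TimeGrid(n_samples=nb + nr, dt=1.0, t0=-float(nb))
    return TemperatureSeries(grid=grid, values=values, **meta)


def generate_cohort(
    table: GroupParamTable | None = None,
    n_psa: int = 11,
    n_hc: int = 9,
    protocol: Protocol | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng_seed=0,
) -> list[CohortRecord]:
    """Generate a labelled cohort of subject x ROI recordings.

    Defaults (11 PsA, 9 HC, 14 ROIs) give 280 curves: 154 PsA + 126 HC.
    All randomness flows from ``rng_seed`` through a spawned seed tree,
    so identical seeds give byte-identical cohorts.
    """
    if n_psa < 1 or n_hc < 1:
        raise ValueError("cohort needs at least one subject per group")
    table = table or default_group_params()
    protocol = protocol or Protocol()
    root = np.random.SeedSequence(rng_seed)
    records: list[CohortRecord] = []
    subjects = [("PsA", f"PsA{i + 1:02d}") for i in range(n_psa)] + [
        ("HC", f"HC{i + 1:02d}") for i in range(n_hc)
    ]
    for (group, subject_id), seq in zip(subjects, root.spawn(len(subjects))):
        rng = np.random.default_rng(seq)
        T = rng.normal(BASAL_MEAN, BASAL_SD)
        r = _truncated_normal(rng, REFERENCE_MEAN, REFERENCE_SD, 1e-6, np.inf)
        ref = ReferenceSignal(T=float(T), y0=float(T - r))
        for roi in ROI_LABELS:
            params = draw_params(table, group, roi, rng)
            series = generate_curve(
                params,
                ref,
                protocol,
                noise_sd,
                rng,
                roi_label=roi,
                subject_id=subject_id,
                group_label=group,
            )
            records.append(
                CohortRecord(
                    subject_id=subject_id,
                    group_label=group,
                    roi_label=roi,
                    series=series,
                    reference=ref,
                    true_params=params,
                )
            )
    return records


def cohort_truth_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Tidy ground-truth table (one row per record)."""
    rows = []
    for rec in records:
        p = rec.true_params
        rows.append(
            {
                "subject": rec.subject_id,
                "group": rec.group_label,
                "roi": rec.roi_label,
                "T": rec.reference.T,
                "y0": rec.reference.y0,
                "r": rec.reference.r,
                "lt": None if p is None else p.lag_time,
                "a": None if p is None else p.pole,
                "d": None if p is None else p.disturbance,
                "k": None if p is None else p.integral_gain,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(
    records: list[CohortRecord], out_dir, protocol: Protocol | None = None
) -> list[Path]:
    """Write per-subject CSVs (time_s + one column per ROI) and a truth sidecar.

    The CSV dialect is exactly what :func:`thermofit.preprocessing.read_roi_csv`
    consumes, so exports round-trip bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protocol = protocol or Protocol()
    by_subject: dict[str, list[CohortRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    paths: list[Path] = []
    for subject_id, recs in by_subject.items():
        n = recs[0].series.grid.n_samples
        data = {"time_s": np.arange(n) * protocol.dt_seconds}
        for rec in recs:
            data[rec.roi_label] = rec.series.values
        path = out_dir / f"{subject_id}.csv"
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
        paths.append(path)
    truth = cohort_truth_frame(records)
    sidecar = out_dir / "ground_truth.json"
    sidecar.write_text(json.dumps(truth.to_dict(orient="records"), indent=1))
    paths.append(sidecar)
    return paths
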