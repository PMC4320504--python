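"""End-to-end pipeline: synthesize -> preprocess -> fit -> exclude -> stats.

Each stage is an importable function over the library; :func:`run_pipeline`
chains them, writes every intermediate artifact under the output directory
and emits a machine-readable run report.  All randomness flows from the
single configured seed, so identical configurations give byte-identical
reports.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .cohort import (
    CohortRecord,
    default_group_params,
    generate_cohort,
    write_cohort,
)
from .estimation import SearchSpace, exclude_poor_fits, fit_curve
from .preprocessing import (
    compute_reference,
    deviation_transform,
    read_roi_csv,
    segment_phases,
    smooth,
)
from .series import Protocol, TimeGrid
from .stats import (
    classify_regions,
    fit_region_classifier,
    region_stats,
    roc_cutoff,
)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "validate_config",
    "run_pipeline",
    "fit_records",
    "fits_frame",
]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


def _jsonable(obj):
    """Recursively convert to JSON-safe types (NaN/inf -> None)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    if isinstance(obj, (int, np.integer, bool, str)) or obj is None:
        return obj
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    baseline_samples: int = 9
    exercise_samples: int = 12
    recovery_samples: int = 30
    sampling_rate_hz: float = 0.1

    def to_protocol(self) -> Protocol:
        return Protocol(**self.model_dump())


class BoundsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lt: tuple[float, float] = (0.0, 22.0)
    a: tuple[float, float] = (0.01, 30.0)
    d: tuple[float, float] = (-5.0, 10.0)
    k: tuple[float, float] = (-5.0, 100.0)

    def to_space(self) -> SearchSpace:
        return SearchSpace(
            lt_bounds=self.lt, a_bounds=self.a, d_bounds=self.d, k_bounds=self.k
        )


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_psa: int = Field(default=11, ge=1)
    n_hc: int = Field(default=9, ge=1)
    noise_sd: float = Field(default=0.04, ge=0.0)


class PipelineConfig(BaseModel):
    """Validated settings; defaults reproduce the study's stated protocol."""

    model_config = ConfigDict(extra="forbid")
    protocol: ProtocolConfig = ProtocolConfig()
    bounds: BoundsConfig = BoundsConfig()
    cohort: CohortConfig = CohortConfig()
    smoothing_span: int = 5
    exclusion_threshold: float = 1.0
    seed: int = 0
    input_dir: str | None = None  # read existing exports instead of generating
    out_dir: str = "results/run"

    @field_validator("smoothing_span")
    @classmethod
    def _odd_span(cls, v: int) -> int:
        if v < 1 or v % 2 == 0:
            raise ValueError("smoothing_span must be odd and >= 1")
        return v


def validate_config(path) -> PipelineConfig:
    """Parse + schema-validate a YAML/JSON config; empty file -> defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return PipelineConfig(**data)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def fit_records(
    records: list[CohortRecord],
    protocol: Protocol,
    space: SearchSpace,
    span: int = 5,
) -> list[CohortRecord]:
    """Preprocess and fit every record in place (smooth, segment, fit)."""
    for rec in records:
        sm_series = smooth(rec.series, span)
        baseline, recovery = segment_phases(sm_series, protocol)
        # re-grid to sample units so rate parameters stay per-sample
        recovery = type(recovery)(
            grid=TimeGrid(n_samples=recovery.grid.n_samples, dt=1.0, t0=0.0),
            values=recovery.values,
            roi_label=recovery.roi_label,
            subject_id=recovery.subject_id,
            group_label=recovery.group_label,
        )
        ref = compute_reference(baseline, recovery)
        dev = deviation_transform(recovery, ref)
        rec.fit = fit_curve(dev, ref, space)
        rec.reference = ref
    return records


def fits_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Tidy fitted-parameter table, one row per record."""
    rows = []
    for rec in records:
        f = rec.fit
        if f is None:
            continue
        rows.append(
            {
                "subject": rec.subject_id,
                "group": rec.group_label,
                "roi": rec.roi_label,
                "lt": f.params.lag_time,
                "a": f.params.pole,
                "d": f.params.disturbance,
                "k": f.params.integral_gain,
                "cost": f.cost,
                "n_points": f.n_points,
                "converged": f.converged,
                "excluded": f.excluded,
            }
        )
    return pd.DataFrame(rows)


def _stats_rows(stats_list) -> list[dict]:
    return [
        {
            "roi": s.roi_label,
            "parameter": s.parameter,
            "psa_mean": s.psa_mean,
            "psa_sd": s.psa_sd,
            "hc_mean": s.hc_mean,
            "hc_sd": s.hc_sd,
            "ranksum": s.ranksum,
            "z": s.z,
            "p_value": s.p_value,
            "significant": s.significant,
        }
        for s in stats_list
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = config.protocol.to_protocol()
    space = config.bounds.to_space()
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "stages": {},
    }

    # stage 1: synthesize (or locate) the cohort exports
    if config.input_dir is None:
        records = generate_cohort(
            default_group_params(),
            n_psa=config.cohort.n_psa,
            n_hc=config.cohort.n_hc,
            protocol=protocol,
            noise_sd=config.cohort.noise_sd,
            rng_seed=config.seed,
        )
        cohort_dir = out / "cohort"
        write_cohort(records, cohort_dir, protocol)
        input_dir = cohort_dir
    else:
        input_dir = Path(config.input_dir)
        records = None
    report["stages"]["cohort"] = {"input_dir": str(input_dir)}

    # stage 2: ingest the written exports (every number downstream is
    # traceable to these files), carrying subject/group labels
    labels = {}
    if records is not None:
        for rec in records:
            labels[rec.subject_id] = rec.group_label
    ingested: list[CohortRecord] = []
    csv_paths = sorted(p for p in input_dir.glob("*.csv"))
    if not csv_paths:
        raise ConfigError(f"no CSV exports found in {input_dir}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for path in csv_paths:
            subject = path.stem
            group = labels.get(subject, "PsA" if subject.startswith("PsA") else "HC")
            for series in read_roi_csv(path, protocol):
                series = type(series)(
                    grid=TimeGrid(
                        n_samples=series.grid.n_samples, dt=1.0, t0=0.0
                    ),
                    values=series.values,
                    roi_label=series.roi_label,
                    subject_id=subject,
                    group_label=group,
                )
                ingested.append(
                    CohortRecord(
                        subject_id=subject,
                        group_label=group,
                        roi_label=series.roi_label,
                        series=series,
                        reference=None,  # measured during preprocessing
                    )
                )
    report["stages"]["ingest"] = {"curves_in": len(ingested)}

    # stage 3: preprocess + fit
    fit_records(ingested, protocol, space, config.smoothing_span)
    fits = fits_frame(ingested)
    fits.to_csv(out / "fits.csv", index=False)

    # stage 4: exclusion
    all_fits = [rec.fit for rec in ingested]
    exclude_poor_fits(all_fits, config.exclusion_threshold)
    fits = fits_frame(ingested)
    fits.to_csv(out / "fits.csv", index=False)
    retained = fits[~fits["excluded"]]
    retained.to_csv(out / "fits_retained.csv", index=False)
    fit_json = {
        f"{rec.subject_id}/{rec.roi_label}": {
            "params": rec.fit.params.as_array().tolist(),
            "init": rec.fit.init_params.as_array().tolist()
            if rec.fit.init_params
            else None,
            "cost": rec.fit.cost,
            "converged": rec.fit.converged,
            "excluded": rec.fit.excluded,
        }
        for rec in ingested
    }
    (out / "fits.json").write_text(
        json.dumps(_jsonable(fit_json), indent=1, sort_keys=True)
    )
    excl_counts = (
        fits[fits["excluded"]].groupby("group").size().to_dict()
        if fits["excluded"].any()
        else {}
    )
    report["stages"]["fit"] = {
        "curves_fit": int(len(fits)),
        "excluded": {g: int(c) for g, c in sorted(excl_counts.items())},
        "retained": int(len(retained)),
    }

    # stage 5: group comparisons (per ROI and pooled), on retained fits
    stats_rows: list[dict] = []
    significant: list[str] = []
    if len(retained) and retained["group"].nunique() == 2:
        for roi, sub in retained.groupby("roi"):
            if sub["group"].nunique() < 2:
                continue
            stats_rows.extend(_stats_rows(region_stats(sub, roi)))
        pooled = _stats_rows(region_stats(retained, "all 14 ROIs"))
        stats_rows.extend(pooled)
        significant = sorted(
            {(r["roi"], r["parameter"]) for r in stats_rows if r["significant"]}
        )
        significant = [f"{roi}:{p}" for roi, p in significant]
    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(out / "group_stats.csv", index=False)
    report["stages"]["stats"] = {"significant": significant}

    # stage 6: per-region classification (logistic + ROC + confusion)
    classification: dict = {}
    for roi, sub in retained.groupby("roi"):
        if (sub["group"] == "PsA").sum() < 2 or (sub["group"] == "HC").sum() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_region_classifier(sub)
            roc = roc_cutoff(model.fitted_probs, model.labels)
            cm = classify_regions(model.fitted_probs, model.labels, roc.cutoff)
        classification[roi] = {
            "coefficients": model.coef,
            "odds_ratios": model.odds_ratios,
            "wald": model.wald,
            "separated": model.separated,
            "cutoff": roc.cutoff,
            "auc": roc.auc,
            "confusion_pct": cm.matrix.tolist(),
            "correct_pct": cm.correct_pct,
        }
    best_roi = max(classification, key=lambda r: classification[r]["auc"], default=None)
    report["stages"]["classify"] = {
        "regions": sorted(classification),
        "best_region": best_roi,
        "best": classification.get(best_roi),
    }
    (out / "classification.json").write_text(
        json.dumps(_jsonable(classification), indent=1, sort_keys=True)
    )

    report_path = out / "report.json"
    report = _jsonable(report)
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
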