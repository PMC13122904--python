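"""File formats: design configs, enrollment logs, interim summaries, reports.

Design configs are YAML (or JSON) documents.  The researcher's confidence
may be declared on either elicitation scale, with the scale stated
explicitly::

    n_target: 1355
    horizon_T: 48
    time_unit: months
    confidence: {scale: ten, value: 3}     # 1-10 scale, divided by 10
    # or: confidence: {scale: unit, value: 0.3}
    categories:
      - {label: NW, p0: 0.45}
      - {label: H,  p0: 0.15}
    rubr_target: 0.6
    draws: 10000
    seed: 42
    study_start: 2013-02-01   # only needed for date-based enrollment CSVs

Enrollment CSVs carry one row per subject with ``subject_id``, either
``enroll_time`` (study units) or ``enroll_date`` (ISO-8601, converted using
``study_start`` and ``time_unit``: days, or months = days / 30.4375), and
one 0/1 column per category.  Interim summaries (the DSMB-report form) are
CSV or JSON with ``interim_index``, ``m``, ``t_m`` and one count column per
category.  Reports are versioned JSON documents.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import CategorySpec, InterimData, TrialDesign, validate_interims_ordered
from .exceptions import ValidationError
from .synthetic import EnrollmentLog, SyntheticTrialConfig

__all__ = [
    "DesignConfig",
    "read_design",
    "read_synth_config",
    "read_enrollment_csv",
    "read_interim_summary",
    "write_report",
    "read_report",
    "validate_report",
]

SCHEMA_VERSION = "1.0"
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class DesignConfig:
    """A parsed design document: the TrialDesign plus run settings."""

    design: TrialDesign
    time_unit: str = "months"
    study_start: Optional[_dt.date] = None
    draws: int = 10_000
    seed: Optional[int] = None
    extras: dict = field(default_factory=dict)


def _load_document(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _normalize_confidence(doc: dict) -> float:
    conf = doc.get("confidence")
    if conf is None and "confidence_P" in doc:
        conf = {"scale": "unit", "value": doc["confidence_P"]}
    if not isinstance(conf, dict) or "scale" not in conf or "value" not in conf:
        raise ValidationError(
            "design must declare confidence as {scale: ten|unit, value: ...}"
        )
    scale, value = conf["scale"], float(conf["value"])
    if scale in ("ten", "1-10"):
        P = value / 10.0
    elif scale in ("unit", "0-1"):
        P = value
    else:
        raise ValidationError(f"unknown confidence scale {scale!r}")
    if not 0.0 <= P <= 1.0:
        raise ValidationError(f"confidence normalizes to {P}, outside [0, 1]")
    return P


def read_design(path) -> DesignConfig:
    """Parse a YAML/JSON trial-design document."""
    doc = _load_document(path)
    if not isinstance(doc, dict):
        raise ValidationError(f"design document {path} is not a mapping")
    P = _normalize_confidence(doc)
    categories = tuple(
        CategorySpec(
            label=str(c["label"]),
            prior_rate_p0=float(c.get("p0", c.get("prior_rate_p0"))),
            target_rate=c.get("target_rate"),
        )
        for c in doc.get("categories", [])
    )
    design = TrialDesign(
        n_target=int(doc["n_target"]),
        horizon_T=float(doc["horizon_T"]),
        confidence_P=P,
        categories=categories,
        rubr_target=(None if doc.get("rubr_target") is None else float(doc["rubr_target"])),
    )
    start = doc.get("study_start")
    if isinstance(start, str):
        start = _dt.date.fromisoformat(start)
    known = {
        "n_target", "horizon_T", "confidence", "confidence_P", "categories",
        "rubr_target", "time_unit", "study_start", "draws", "seed",
    }
    return DesignConfig(
        design=design,
        time_unit=str(doc.get("time_unit", "months")),
        study_start=start,
        draws=int(doc.get("draws", 10_000)),
        seed=doc.get("seed"),
        extras={k: v for k, v in doc.items() if k not in known},
    )


def read_synth_config(path) -> SyntheticTrialConfig:
    """Parse a YAML/JSON synthetic-trial ground-truth document."""
    doc = _load_document(path)
    return SyntheticTrialConfig(
        theta_true=float(doc["theta_true"]),
        p_true={str(k): float(v) for k, v in dict(doc.get("p_true", {})).items()},
        horizon_T=float(doc.get("horizon_T", 1.0)),
        n_max=(None if doc.get("n_max") is None else int(doc["n_max"])),
        overlap_mode=str(doc.get("overlap_mode", "independent")),
        seed=doc.get("seed"),
    )


def _dates_to_times(dates: pd.Series, config: DesignConfig) -> np.ndarray:
    if config.study_start is None:
        raise ValidationError(
            "enroll_date column requires study_start in the design config"
        )
    try:
        parsed = pd.to_datetime(dates, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable enroll_date: {exc}") from None
    start = pd.Timestamp(config.study_start)
    days = (parsed - start).dt.total_seconds().to_numpy() / 86_400.0
    if (days < 0).any():
        row = int(np.flatnonzero(days < 0)[0])
        raise ValidationError(
            f"enroll_date before study start at row {row} ({dates.iloc[row]})"
        )
    if config.time_unit == "days":
        return days
    if config.time_unit == "months":
        return days / DAYS_PER_MONTH
    raise ValidationError(f"unsupported time_unit {config.time_unit!r}")


def read_enrollment_csv(path, config: DesignConfig) -> EnrollmentLog:
    """Parse a subject-level enrollment CSV against the declared design.

    Rows are sorted by enrollment time; ties keep file order.
    """
    frame = pd.read_csv(path)
    labels = list(config.design.labels)
    if "subject_id" not in frame.columns:
        raise ValidationError("enrollment CSV missing required column 'subject_id'")
    missing = [c for c in labels if c not in frame.columns]
    if missing:
        raise ValidationError(f"enrollment CSV missing category columns: {missing}")

    if "enroll_time" in frame.columns:
        times = frame["enroll_time"].astype(float).to_numpy()
        if (times < 0).any():
            row = int(np.flatnonzero(times < 0)[0])
            raise ValidationError(f"negative enroll_time at row {row}")
    elif "enroll_date" in frame.columns:
        times = _dates_to_times(frame["enroll_date"], config)
    else:
        raise ValidationError(
            "enrollment CSV needs an 'enroll_time' or 'enroll_date' column"
        )

    for c in labels:
        vals = frame[c].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"flag outside {{0,1}} in column {c!r} at row {row} "
                f"(value {vals[row]!r})"
            )

    out = pd.DataFrame({"subject_id": frame["subject_id"], "enroll_time": times})
    for c in labels:
        out[c] = frame[c].astype(np.int64)
    out = out.sort_values("enroll_time", kind="stable").reset_index(drop=True)
    return EnrollmentLog(frame=out, categories=tuple(labels))


def read_interim_summary(path, design: TrialDesign) -> list[InterimData]:
    """Parse aggregated interim summaries (CSV or JSON) into InterimData.

    Rows must carry ``m``, ``t_m`` and one count column per design
    category; they are validated (counts <= m, non-decreasing t_m) and
    returned in look order.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        frame = pd.DataFrame(doc)
    else:
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            frame = pd.DataFrame()
    if frame.empty:
        warnings.warn(f"interim summary {path} is empty", UserWarning, stacklevel=2)
        return []
    for col in ("m", "t_m"):
        if col not in frame.columns:
            raise ValidationError(f"interim summary missing column {col!r}")
    interims = []
    for _, row in frame.iterrows():
        counts = {}
        for label in design.labels:
            if label not in frame.columns:
                raise ValidationError(f"interim summary missing count column {label!r}")
            counts[label] = int(row[label])
        interims.append(InterimData(m=int(row["m"]), t_m=float(row["t_m"]), counts=counts))
    validate_interims_ordered(interims)
    return interims


def _design_block(design: TrialDesign) -> dict:
    return {
        "n_target": design.n_target,
        "horizon_T": design.horizon_T,
        "confidence_P": design.confidence_P,
        "rubr_target": design.rubr_target,
        "categories": [
            {"label": c.label, "p0": c.prior_rate_p0, "target_rate": c.target_rate}
            for c in design.categories
        ],
    }


def write_report(
    results: Sequence,
    path,
    design: Optional[TrialDesign] = None,
    include_draws: bool = False,
) -> dict:
    """Serialize fitted results as a versioned JSON report.

    ``results`` is a sequence of AccrualUBRResults (one per interim look).
    Per-draw arrays are included only when ``include_draws`` is set.
    Returns the document that was written.
    """
    results = list(results)
    if design is None and results:
        design = results[0].model.design
    doc = {
        "schema_version": SCHEMA_VERSION,
        "design": _design_block(design) if design is not None else None,
        "settings": {
            "draws": results[0].prediction.s if results else 0,
            "seed": results[0].seed if results else None,
            "method": results[0].method if results else None,
        },
        "interims": [res.to_report_block(index=i) for i, res in enumerate(results, 1)],
    }
    if include_draws:
        for res, block in zip(results, doc["interims"]):
            pred = res.prediction
            block["draws"] = {
                "sample_size": pred.sample_size_draws.tolist(),
                "rubr": pred.rubr_draws.tolist(),
            }
    text = json.dumps(doc, indent=2, default=_json_default)
    Path(path).write_text(text)
    return json.loads(text)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def validate_report(doc: dict) -> None:
    """Check a report document against the shipped schema; raise on failure."""
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError("report missing or unknown schema_version")
    if "interims" not in doc or not isinstance(doc["interims"], list):
        raise ValidationError("report missing 'interims' list")
    for block in doc["interims"]:
        for key in ("index", "m", "t_m", "sample_size", "rubr", "prob_meeting"):
            if key not in block:
                raise ValidationError(f"interim block missing {key!r}")
        for key in ("sample_size", "rubr"):
            summ = block[key]
            for stat in ("mean", "median", "ci95"):
                if stat not in summ:
                    raise ValidationError(f"{key} summary missing {stat!r}")
            if len(summ["ci95"]) != 2:
                raise ValidationError(f"{key} ci95 must have two endpoints")
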