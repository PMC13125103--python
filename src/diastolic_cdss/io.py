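"""Reading and writing studies, configuration, and reports.

Canonical on-disk study format is JSON, one study per file, mirroring the
:class:`~diastolic_cdss.model.StressStudy` schema (the measurement set is
hierarchical — two stages — so JSON is the natural carrier).  CSV is
supported through a small dialect description:

* ``long`` dialect (default): columns ``parameter, stage, value`` with
  stage in {rest, peak, study}; demographics travel under stage ``study``.
  Column order is irrelevant; rows may come in any order.
* ``wide`` dialect: a single row per study with columns ``rest.<param>`` /
  ``peak.<param>`` plus bare demographic columns.

A dialect may rename file columns to canonical parameters via
``column_map`` and declare per-column units; a declared unit that differs
from the canonical unit for that parameter is a hard error (no silent
conversion at input).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from .calc import derive_all
from .model import (
    EchoMeasurementSet,
    PatientDemographics,
    StressStudy,
    ThresholdConfig,
    validate_study,
)
from .report import StructuredReport, build_report, render_report
from .rules import (
    Rule,
    build_default_rulebase,
    cluster_statements,
    evaluate_study,
    rulebase_from_dicts,
    rulebase_to_dicts,
)

log = logging.getLogger("diastolic_cdss")

_DEMO_FIELDS = set(PatientDemographics.model_fields)
_MEAS_FIELDS = set(EchoMeasurementSet.model_fields) - {"stage", "overrides"}

#: canonical unit per measurement column, used to reject unit mismatches
CANONICAL_UNITS: Dict[str, str] = {
    "ao_diam": "cm", "la_diam": "cm", "ivs": "cm", "pw": "cm",
    "lvidd": "cm", "lvids": "cm", "rv_diam": "cm", "lvot_diam": "cm",
    "lvedv": "mL", "lvesv": "mL", "lav": "mL", "vti": "cm",
    "e_wave": "cm/s", "a_wave": "cm/s", "e_prime": "cm/s",
    "a_prime": "cm/s", "tr_vel": "m/s", "mr_vel": "m/s",
    "ivc_max": "mm", "ivc_min": "mm", "tapse": "mm",
    "minute_distance": "cm/min", "heart_rate": "bpm",
    "sbp": "mmHg", "dbp": "mmHg", "weight": "kg", "height": "cm",
}


class StudyParseError(ValueError):
    """File-level problem (parse failure, unknown column, unit mismatch)
    with location context."""


class StudyFileDialect(BaseModel):
    """How a CSV file maps onto the canonical study schema."""

    layout: str = "long"  # long | wide
    column_map: Dict[str, str] = Field(default_factory=dict)  # file -> canonical
    units: Dict[str, str] = Field(default_factory=dict)  # canonical -> unit

    def canonical(self, name: str) -> str:
        return self.column_map.get(name, name)

    def check_units(self) -> None:
        for param, unit in self.units.items():
            expected = CANONICAL_UNITS.get(param)
            if expected is not None and unit != expected:
                raise StudyParseError(
                    f"unit mismatch for {param!r}: file declares {unit!r}, "
                    f"canonical unit is {expected!r}")


def read_study(path: Union[str, Path],
               dialect: Optional[StudyFileDialect] = None) -> StressStudy:
    """Read one study from JSON (canonical) or CSV (via dialect)."""
    path = Path(path)
    if not path.exists():
        raise StudyParseError(f"{path}: no such file")
    if path.suffix.lower() == ".json":
        try:
            return StressStudy.model_validate_json(path.read_text())
        except ValidationError as exc:
            raise StudyParseError(f"{path}: invalid study JSON: {exc}") from exc
    if path.suffix.lower() == ".csv":
        return _read_csv_study(path, dialect or StudyFileDialect())
    raise StudyParseError(f"{path}: unsupported study format {path.suffix!r}")


def write_study(study: StressStudy, path: Union[str, Path]) -> None:
    Path(path).write_text(study.model_dump_json(indent=2, exclude_none=True) + "\n")


def _classify(name: str, path: Path, row: object) -> str:
    if name in _DEMO_FIELDS:
        return "demo"
    if name in _MEAS_FIELDS:
        return "meas"
    raise StudyParseError(f"{path} (row {row}): unknown parameter {name!r}")


def _read_csv_study(path: Path, dialect: StudyFileDialect) -> StressStudy:
    dialect.check_units()
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise StudyParseError(f"{path}: CSV parse failure: {exc}") from exc

    demo: Dict[str, object] = {}
    stages: Dict[str, Dict[str, object]] = {"rest": {}, "peak": {}}

    if dialect.layout == "long":
        required = {"parameter", "stage", "value"}
        if not required <= set(df.columns):
            raise StudyParseError(
                f"{path}: long dialect requires columns {sorted(required)}, "
                f"found {list(df.columns)}")
        for row in df.itertuples():
            name = dialect.canonical(str(row.parameter))
            stage = str(row.stage)
            if stage == "study":
                if name not in _DEMO_FIELDS:
                    raise StudyParseError(
                        f"{path} (row {row.Index}): {name!r} is not a "
                        "study-level field")
                demo[name] = row.value
            elif stage in stages:
                if _classify(name, path, row.Index) != "meas":
                    raise StudyParseError(
                        f"{path} (row {row.Index}): demographic field "
                        f"{name!r} must use stage 'study'")
                stages[stage][name] = float(row.value)
            else:
                raise StudyParseError(
                    f"{path} (row {row.Index}): unknown stage {stage!r}")
    elif dialect.layout == "wide":
        if len(df) != 1:
            raise StudyParseError(
                f"{path}: wide dialect expects exactly one row, got {len(df)}")
        row = df.iloc[0]
        for col in df.columns:
            name = dialect.canonical(str(col))
            value = row[col]
            if pd.isna(value):
                continue
            if "." in name:
                stage, param = name.split(".", 1)
                if stage not in stages:
                    raise StudyParseError(f"{path}: unknown stage prefix {stage!r}")
                if param not in _MEAS_FIELDS:
                    raise StudyParseError(f"{path}: unknown parameter {param!r}")
                stages[stage][param] = float(value)
            else:
                if name not in _DEMO_FIELDS:
                    raise StudyParseError(f"{path}: unknown column {name!r}")
                demo[name] = value
    else:
        raise StudyParseError(f"{path}: unknown dialect layout {dialect.layout!r}")

    missing = [p for p in ("e_prime", "e_wave") if p not in stages["rest"]]
    if missing:
        raise StudyParseError(
            f"{path}: required parameter(s) missing: {', '.join(missing)}")
    try:
        return StressStudy(
            demographics=PatientDemographics(**demo),
            rest=EchoMeasurementSet(stage="rest", **stages["rest"]),
            peak=EchoMeasurementSet(stage="peak", **stages["peak"]),
        )
    except ValidationError as exc:
        raise StudyParseError(f"{path}: invalid study content: {exc}") from exc


# ---------------------------------------------------------------------------
# configuration

def load_thresholds(path: Union[str, Path, None]) -> ThresholdConfig:
    """Threshold overrides from a YAML/JSON mapping, merged over defaults."""
    if path is None:
        return ThresholdConfig()
    payload = yaml.safe_load(Path(path).read_text())
    if payload is None:
        return ThresholdConfig()
    if not isinstance(payload, dict):
        raise StudyParseError(f"{path}: threshold config must be a mapping")
    unknown = set(payload) - set(ThresholdConfig.model_fields)
    if unknown:
        raise StudyParseError(
            f"{path}: unknown threshold name(s): {', '.join(sorted(unknown))}")
    return ThresholdConfig(**payload)


def load_rulebase(path: Union[str, Path],
                  thresholds: Optional[ThresholdConfig] = None) -> List[Rule]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, list):
        raise StudyParseError(f"{path}: rulebase file must be a list of rules")
    return rulebase_from_dicts(payload, thresholds)


def save_rulebase(rules: Sequence[Rule], path: Union[str, Path]) -> None:
    Path(path).write_text(
        yaml.safe_dump(rulebase_to_dicts(rules), sort_keys=False))


# ---------------------------------------------------------------------------
# pipeline

class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def run_pipeline(
    study: StressStudy,
    thresholds: Optional[ThresholdConfig] = None,
    rules: Optional[Sequence[Rule]] = None,
) -> StructuredReport:
    """validate -> derive -> infer -> cluster -> report, with stage logs."""
    thresholds = thresholds or ThresholdConfig()
    rules = list(rules) if rules is not None else build_default_rulebase(thresholds)

    t0 = time.perf_counter()
    findings = validate_study(study)
    errors = [f for f in findings if f.severity.value == "error"]
    if errors:
        raise PipelineError(
            "validate", "; ".join(f.message for f in errors))
    log.info("validate: %d finding(s), %.1f ms",
             len(findings), (time.perf_counter() - t0) * 1e3)

    t0 = time.perf_counter()
    try:
        rest, peak, pair = derive_all(study)
    except ValueError as exc:
        raise PipelineError("derive", str(exc)) from exc
    log.info("derive: %.1f ms", (time.perf_counter() - t0) * 1e3)

    t0 = time.perf_counter()
    evaluations = evaluate_study(rules, study, thresholds,
                                 derived=(rest, peak, pair))
    conclusion = cluster_statements(evaluations)
    log.info("infer: %d evaluation(s), %.1f ms",
             len(evaluations), (time.perf_counter() - t0) * 1e3)

    return build_report(study, rest, peak, pair, evaluations, conclusion,
                        rules, thresholds)


def run_batch(
    studies: Sequence[StressStudy],
    thresholds: Optional[ThresholdConfig] = None,
    rules: Optional[Sequence[Rule]] = None,
) -> List[StructuredReport]:
    """Order-preserving batch; each study is computed independently."""
    return [run_pipeline(s, thresholds, rules) for s in studies]


__all__ = [
    "StudyFileDialect", "StudyParseError", "PipelineError",
    "read_study", "write_study", "load_thresholds", "load_rulebase",
    "save_rulebase", "run_pipeline", "run_batch", "render_report",
]
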