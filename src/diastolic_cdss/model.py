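"""Typed data model and input validation for stress-echo studies.

A :class:`StressStudy` is the unit of analysis: patient demographics plus two
:class:`EchoMeasurementSet` objects, one acquired at rest and one at peak
semi-supine bicycle exercise.  Measurement fields carry the units of the
clinical worksheet (lengths in cm except TAPSE and IVC diameters in mm,
velocities in cm/s except the regurgitant jets TR/MR in m/s); unit
conversions happen inside the calculation engine, never at input.

Validation is finding-based rather than exception-based: every range or
consistency violation is reported as a :class:`ValidationFinding`, and only
error-severity findings block downstream computation.  Optional fields that
are absent stay absent (``None``) — dependent derived indices become absent
and dependent rules evaluate indeterminate, rather than silently zero.
"""

from __future__ import annotations

import enum
from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field


class Stage(str, enum.Enum):
    rest = "rest"
    peak = "peak"


class Sex(str, enum.Enum):
    female = "female"
    male = "male"
    unspecified = "unspecified"


class Severity(str, enum.Enum):
    error = "error"
    warning = "warning"


class ValidationFinding(BaseModel):
    """One range-limit or logical-consistency violation."""

    model_config = ConfigDict(frozen=True)

    field: str
    message: str
    severity: Severity = Severity.error
    value: Optional[float] = None
    allowed: Optional[Tuple[float, float]] = None
    stage: Optional[Stage] = None


class PatientDemographics(BaseModel):
    patient_id: str = "anonymous"
    birth_year: Optional[int] = None
    age: Optional[int] = None
    sex: Sex = Sex.unspecified
    weight: float = Field(..., gt=0, description="body weight, kg")
    height: float = Field(..., gt=0, description="body height, cm")


class EchoMeasurementSet(BaseModel):
    """Raw echocardiographic measurements for one stage.

    All measurement fields are optional; computation degrades gracefully
    when a field is absent.  ``overrides`` carries manual-entry values for
    derived indices (keyed by the derived-index field name, e.g. ``lvmm`` or
    ``svr``); an override replaces the computed value and is flagged as
    manual in the derived set.
    """

    stage: Stage

    # 2D geometry, cm
    ao_diam: Optional[float] = None
    la_diam: Optional[float] = None
    ivs: Optional[float] = None
    pw: Optional[float] = None
    lvidd: Optional[float] = None
    lvids: Optional[float] = None
    rv_diam: Optional[float] = None
    lvot_diam: Optional[float] = None

    # volumes, mL
    lvedv: Optional[float] = None
    lvesv: Optional[float] = None
    lav: Optional[float] = None

    # spectral / tissue Doppler, cm/s (TR and MR in m/s); VTI in cm
    vti: Optional[float] = None
    e_wave: Optional[float] = None
    a_wave: Optional[float] = None
    e_prime: Optional[float] = None
    a_prime: Optional[float] = None
    tr_vel: Optional[float] = None
    mr_vel: Optional[float] = None

    # right heart, mm
    ivc_max: Optional[float] = None
    ivc_min: Optional[float] = None
    tapse: Optional[float] = None

    # rate / pressure
    minute_distance: Optional[float] = None  # cm/min
    heart_rate: Optional[float] = None  # bpm
    sbp: Optional[float] = None  # mmHg
    dbp: Optional[float] = None  # mmHg

    overrides: Dict[str, float] = Field(default_factory=dict)


class StressStudy(BaseModel):
    demographics: PatientDemographics
    rest: EchoMeasurementSet
    peak: EchoMeasurementSet
    acquired_at: Optional[str] = None


class ThresholdConfig(BaseModel):
    """Named rule cut-offs.  Every rule predicate references thresholds only
    through this configuration so clinicians can audit and recalibrate
    without code changes."""

    e_over_eprime_high: float = 15.0  # filling-pressure threshold on E/e'
    e_over_eprime_normal: float = 10.0  # normal-pattern upper bound on E/e'
    delta_e_prime_normal: float = 1.5  # cm/s, minimum normal e' augmentation
    tapse_low: float = 17.0  # mm
    pcwp_high: float = 12.0  # mmHg
    vti_low: float = 18.0  # cm
    vti_borderline: float = 22.0  # cm, flow-reserve band (applied at peak)
    svr_high: float = 1200.0  # dyn*s*cm^-5
    trv_high_bernoulli: float = 2.8  # m/s
    trv_high_combo: float = 3.0  # m/s
    lavi_high: float = 34.0  # mL/m^2
    co_low: float = 4.0  # L/min
    ef_preserved: float = 50.0  # %, preserved-EF inclusion bound
    lvsi_high: float = 0.15  # stiffness-index cut-off (package convention)

    zero: float = 0.0  # anchor for sign comparisons (delta e' <= 0)


class DerivedIndexSet(BaseModel):
    """All computed hemodynamic indices for one stage, full internal
    precision.  Absent inputs propagate as ``None``.  ``manual`` lists the
    fields whose values came from measurement-set overrides rather than the
    calculation engine."""

    stage: Stage

    bmi: Optional[float] = None  # kg/m^2
    bsa: Optional[float] = None  # m^2 (unrounded Du Bois)
    ila: Optional[float] = None  # indexed LA diameter, cm/m^2
    edvi: Optional[float] = None  # mL/m^2
    esvi: Optional[float] = None  # mL/m^2
    ef: Optional[float] = None  # %
    sf: Optional[float] = None  # %
    rwt: Optional[float] = None
    lvmm: Optional[float] = None  # g
    ilvmm: Optional[float] = None  # g/m^2
    csa_lvot: Optional[float] = None  # cm^2
    sv: Optional[float] = None  # mL
    isv: Optional[float] = None  # mL/m^2
    hr: Optional[float] = None  # bpm
    co: Optional[float] = None  # L/min
    ci: Optional[float] = None  # L/min/m^2
    md: Optional[float] = None  # cm/min
    e_over_a: Optional[float] = None
    e_over_eprime: Optional[float] = None
    trpg: Optional[float] = None  # mmHg
    mrpg: Optional[float] = None  # mmHg
    ivc_ci: Optional[float] = None  # %
    rap: Optional[float] = None  # mmHg
    map: Optional[float] = None  # mmHg
    svr: Optional[float] = None  # dyn*s*cm^-5
    pcwp: Optional[float] = None  # mmHg (linear E/e' estimator)
    pcwr_ratio: Optional[float] = None  # (E/e')/SV, reported separately
    lavi: Optional[float] = None  # mL/m^2
    lvsi: Optional[float] = None  # (E/e')/LVEDV
    dri: Optional[float] = None  # diastolic reserve index (plug-in slot)

    manual: List[str] = Field(default_factory=list)


class PairIndices(BaseModel):
    """Rest-to-peak indices: e' augmentation and percent dynamics per
    shared parameter (full precision, ``(peak - rest)/rest * 100``)."""

    delta_e_prime: Optional[float] = None  # cm/s
    dynamics: Dict[str, float] = Field(default_factory=dict)
    dri: Optional[float] = None


# Plausibility ranges (field -> inclusive physiologic bounds).  Wide on
# purpose: the check rejects impossible entries (transcription slips, unit
# mix-ups), not unusual physiology.
PLAUSIBILITY_RANGES: Dict[str, Tuple[float, float]] = {
    "ao_diam": (1.5, 6.0),
    "la_diam": (1.5, 7.0),
    "ivs": (0.3, 3.0),
    "pw": (0.3, 3.0),
    "lvidd": (2.0, 8.0),
    "lvids": (1.0, 7.0),
    "rv_diam": (1.0, 6.0),
    "lvot_diam": (1.5, 3.0),
    "lvedv": (20.0, 400.0),
    "lvesv": (5.0, 300.0),
    "lav": (10.0, 200.0),
    "vti": (5.0, 60.0),
    "e_wave": (20.0, 250.0),
    "a_wave": (10.0, 200.0),
    "e_prime": (1.0, 30.0),
    "a_prime": (1.0, 30.0),
    "tr_vel": (0.5, 6.0),
    "mr_vel": (0.1, 7.0),
    "ivc_max": (3.0, 40.0),
    "ivc_min": (0.0, 40.0),
    "tapse": (5.0, 40.0),
    "minute_distance": (200.0, 10000.0),
    "heart_rate": (30.0, 220.0),
    "sbp": (60.0, 260.0),
    "dbp": (30.0, 150.0),
}

#: fields whose value must be strictly positive when present
_POSITIVE_FIELDS = [
    name for name in PLAUSIBILITY_RANGES if name not in ("ivc_min",)
]

#: (field_a, field_b, message) pairs requiring a < b when both present
_ORDER_CHECKS = [
    ("lvids", "lvidd", "lvids < lvidd violated"),
    ("lvesv", "lvedv", "lvesv < lvedv violated"),
]


def validate_demographics(d: PatientDemographics) -> List[ValidationFinding]:
    findings: List[ValidationFinding] = []
    if d.weight <= 0:
        findings.append(ValidationFinding(field="weight", value=d.weight,
                                          message="weight must be > 0 kg"))
    if d.height <= 0:
        findings.append(ValidationFinding(field="height", value=d.height,
                                          message="height must be > 0 cm"))
    if d.age is not None and not (18 <= d.age <= 120):
        findings.append(ValidationFinding(
            field="age", value=float(d.age), allowed=(18, 120),
            message="age outside inclusion range 18-120 years"))
    return findings


def validate_measurements(
    m: EchoMeasurementSet,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
) -> List[ValidationFinding]:
    """Range-limit and logical-consistency checks for one stage.

    Returns one finding per violation; an empty list means the set is
    acceptable.  Never mutates the input.
    """
    ranges = PLAUSIBILITY_RANGES if ranges is None else ranges
    findings: List[ValidationFinding] = []
    stage = m.stage

    for name in _POSITIVE_FIELDS:
        value = getattr(m, name, None)
        if value is not None and value <= 0:
            findings.append(ValidationFinding(
                field=name, value=value, stage=stage,
                message=f"{name} must be strictly positive"))

    for name, (lo, hi) in ranges.items():
        value = getattr(m, name, None)
        if value is None or value <= 0 and name in _POSITIVE_FIELDS:
            continue  # positivity already reported
        if not (lo <= value <= hi):
            findings.append(ValidationFinding(
                field=name, value=value, allowed=(lo, hi), stage=stage,
                message=f"{name}={value:g} outside plausible range "
                        f"[{lo:g}, {hi:g}]"))

    for a, b, msg in _ORDER_CHECKS:
        va, vb = getattr(m, a), getattr(m, b)
        if va is not None and vb is not None and not va < vb:
            findings.append(ValidationFinding(
                field=a, value=va, stage=stage, message=msg))

    if m.ivc_max is not None and m.ivc_min is not None and m.ivc_min > m.ivc_max:
        findings.append(ValidationFinding(
            field="ivc_min", value=m.ivc_min, stage=stage,
            message="ivc_min <= ivc_max violated"))

    if m.minute_distance is None and m.heart_rate is None:
        findings.append(ValidationFinding(
            field="minute_distance", stage=stage, severity=Severity.warning,
            message="neither minute_distance nor heart_rate present; "
                    "flow indices will be absent"))

    return findings


def validate_study(
    s: StressStudy,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
) -> List[ValidationFinding]:
    """Union of per-stage findings plus pair-level consistency checks."""
    findings = validate_demographics(s.demographics)
    if s.rest.stage is not Stage.rest:
        findings.append(ValidationFinding(
            field="rest.stage", message="rest measurement set not labelled "
            f"'rest' (got '{s.rest.stage.value}')"))
    if s.peak.stage is not Stage.peak:
        findings.append(ValidationFinding(
            field="peak.stage", message="peak measurement set not labelled "
            f"'peak' (got '{s.peak.stage.value}')"))
    findings.extend(validate_measurements(s.rest, ranges))
    findings.extend(validate_measurements(s.peak, ranges))
    return findings


def has_errors(findings: List[ValidationFinding]) -> bool:
    return any(f.severity is Severity.error for f in findings)
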