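"""Structured diagnostic reports: value table, criteria grid, conclusions,
rule trace, references.

Rendering is deterministic — identical inputs give byte-identical output —
and the JSON format round-trips losslessly to :class:`StructuredReport`.
Every numeric cell equals the presentation-rounded derived value and every
grid outcome equals the inference-engine outcome; the report never restates
anything the engine did not compute.
"""

from __future__ import annotations

import io as _io
from typing import Dict, List, Optional, Sequence, Tuple

from pydantic import BaseModel, Field

from .calc import presentation_view
from .model import (
    DerivedIndexSet,
    PairIndices,
    Stage,
    StressStudy,
    ThresholdConfig,
)
from .rules import DiagnosticConclusion, Rule, RuleEvaluation

FORMATS = ("text", "markdown", "json")


class UsageError(ValueError):
    pass


#: value-table layout: (parameter key, row caption, unit)
ROW_SPECS: List[Tuple[str, str, str]] = [
    ("ao_diam", "Ascending aorta diameter (Ao)", "cm"),
    ("la_diam", "Left atrial diameter (LA)", "cm"),
    ("ila", "Indexed left atrial diameter (iLA)", "cm/m2"),
    ("ivs", "Interventricular septal thickness (IVS)", "cm"),
    ("pw", "Posterior wall thickness (PW)", "cm"),
    ("lvidd", "LV internal diameter, diastole (LVIDd)", "cm"),
    ("lvids", "LV internal diameter, systole (LVIDs)", "cm"),
    ("lvedv", "LV end-diastolic volume (LVEDV)", "mL"),
    ("edvi", "Indexed end-diastolic volume (EDVi)", "mL/m2"),
    ("lvesv", "LV end-systolic volume (LVESV)", "mL"),
    ("esvi", "Indexed end-systolic volume (ESVi)", "mL/m2"),
    ("rv_diam", "Right ventricular diameter (RV)", "cm"),
    ("ef", "Ejection fraction (EF)", "%"),
    ("sf", "Shortening fraction (SF)", "%"),
    ("sv", "Stroke volume (SV)", "mL"),
    ("isv", "Indexed stroke volume (iSV)", "mL/m2"),
    ("lvmm", "LV myocardial mass (LVMM)", "g"),
    ("ilvmm", "Indexed LV myocardial mass (iLVMM)", "g/m2"),
    ("rwt", "Relative wall thickness (RWT)", ""),
    ("lvot_diam", "LV outflow tract diameter (LVOT)", "cm"),
    ("csa_lvot", "Cross-sectional area of LVOT (CSA LVOT)", "cm2"),
    ("vti", "Velocity-time integral (VTI)", "cm"),
    ("e_wave", "Early transmitral flow velocity (E)", "cm/s"),
    ("a_wave", "Late transmitral flow velocity (A)", "cm/s"),
    ("e_over_a", "E/A ratio", ""),
    ("e_prime", "Early diastolic mitral annular velocity (e')", "cm/s"),
    ("a_prime", "Late diastolic mitral annular velocity (a')", "cm/s"),
    ("e_over_eprime", "E/e' ratio", ""),
    ("ivc_max", "Maximum IVC diameter (IVC max)", "mm"),
    ("ivc_min", "Minimum IVC diameter (IVC min)", "mm"),
    ("ivc_ci", "IVC collapsibility index (IVC CI)", "%"),
    ("tr_vel", "Tricuspid regurgitation velocity (TR)", "m/s"),
    ("trpg", "TR pressure gradient (TRPG)", "mmHg"),
    ("mr_vel", "Mitral regurgitation velocity (MR)", "m/s"),
    ("mrpg", "MR pressure gradient (MRPG)", "mmHg"),
    ("lav", "Left atrial volume (LAV)", "mL"),
    ("lavi", "Indexed left atrial volume (LAVi)", "mL/m2"),
    ("hr", "Heart rate (HR)", "bpm"),
    ("co", "Cardiac output (CO)", "L/min"),
    ("ci", "Cardiac index (CI)", "L/min/m2"),
    ("md", "Minute distance (MD)", "cm/min"),
    ("tapse", "Tricuspid annular plane systolic excursion (TAPSE)", "mm"),
    ("dri", "Diastolic reserve index (DRi)", ""),
    ("lvsi", "LV stiffness index (LVSI)", ""),
    ("pcwr_ratio", "Wedge-to-flow ratio (E/e')/SV (PCWR)", "mmHg/mL"),
    ("svr", "Systemic vascular resistance (SVR)", "dyn*s*cm-5"),
    ("pcwp", "Pulmonary capillary wedge pressure (PCWP)", "mmHg"),
    ("rap", "Right atrial pressure estimate (RAP)", "mmHg"),
    ("map", "Mean arterial pressure (MAP)", "mmHg"),
]

_OUTCOME_MARK = {"fired": "Yes", "not_fired": "No", "indeterminate": "-"}


class ValueRow(BaseModel):
    key: str
    label: str
    unit: str
    rest: Optional[float] = None
    peak: Optional[float] = None
    dynamics: Optional[float] = None
    manual: bool = False


class GridRow(BaseModel):
    rule_id: str
    criterion: str
    rest: str  # Yes | No | -
    peak: str


class ReportHeader(BaseModel):
    patient_id: str
    sex: str
    age: Optional[int] = None
    birth_year: Optional[int] = None
    weight: float
    height: float
    bmi: Optional[float] = None
    bsa: Optional[float] = None
    acquired_at: Optional[str] = None


class StructuredReport(BaseModel):
    header: ReportHeader
    values: List[ValueRow]
    grid: List[GridRow]
    conclusions: List[str]
    labels: List[str]
    abnormal_flags: List[str]
    conflicts: List[str]
    insufficient_data: bool = False
    trace: List[RuleEvaluation]
    thresholds: Dict[str, float]
    references: List[str]


def build_report(
    study: StressStudy,
    rest: DerivedIndexSet,
    peak: DerivedIndexSet,
    pair: PairIndices,
    evaluations: Sequence[RuleEvaluation],
    conclusion: DiagnosticConclusion,
    rules: Sequence[Rule],
    thresholds: Optional[ThresholdConfig] = None,
) -> StructuredReport:
    """Assemble the report object from the upstream stage outputs."""
    thresholds = thresholds or ThresholdConfig()
    d = study.demographics
    from .calc import present

    view = presentation_view(rest, peak, study.rest, study.peak)
    manual = set(rest.manual) | set(peak.manual)
    values = []
    for key, label, unit in ROW_SPECS:
        cell = view.get(key, {})
        if cell.get("rest") is None and cell.get("peak") is None:
            continue
        values.append(ValueRow(
            key=key, label=label, unit=unit, rest=cell.get("rest"),
            peak=cell.get("peak"), dynamics=cell.get("dynamics"),
            manual=key in manual))

    by_rule_stage = {(e.rule_id, e.stage): e for e in evaluations}
    grid = []
    for rule in rules:
        if not rule.in_grid:
            continue
        cells = {}
        for stage in (Stage.rest, Stage.peak):
            e = by_rule_stage.get((rule.rule_id, stage))
            cells[stage] = _OUTCOME_MARK.get(e.outcome, "-") if e else "-"
        grid.append(GridRow(
            rule_id=rule.rule_id,
            criterion=rule.criterion_label or rule.statement,
            rest=cells[Stage.rest], peak=cells[Stage.peak]))

    references = sorted({r.guideline_ref for r in rules})

    return StructuredReport(
        header=ReportHeader(
            patient_id=d.patient_id, sex=d.sex.value, age=d.age,
            birth_year=d.birth_year, weight=d.weight, height=d.height,
            bmi=present("bmi", rest.bmi), bsa=present("bsa", rest.bsa),
            acquired_at=study.acquired_at),
        values=values,
        grid=grid,
        conclusions=list(conclusion.statements),
        labels=list(conclusion.labels),
        abnormal_flags=list(conclusion.abnormal_flags),
        conflicts=list(conclusion.conflicts),
        insufficient_data=conclusion.insufficient_data,
        trace=list(evaluations),
        thresholds={k: float(v) for k, v in thresholds.model_dump().items()},
        references=references,
    )


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return "-"
    return f"{x:g}"


def render_report(report: StructuredReport, format: str = "text") -> str:
    """Render to ``text``, ``markdown`` or ``json``.  Unknown formats raise
    :class:`UsageError`."""
    if format == "json":
        return report.model_dump_json(indent=2) + "\n"
    if format not in FORMATS:
        raise UsageError(
            f"unknown report format {format!r}; expected one of {FORMATS}")

    md = format == "markdown"
    out = _io.StringIO()
    h = report.header

    def heading(text: str) -> None:
        if md:
            out.write(f"\n## {text}\n\n")
        else:
            out.write(f"\n{text}\n{'-' * len(text)}\n")

    title = "Diastolic stress echocardiography report"
    out.write(f"# {title}\n" if md else f"{title}\n{'=' * len(title)}\n")
    out.write(
        f"\nPatient: {h.patient_id}  Sex: {h.sex}  Age: {h.age or '-'}  "
        f"Birth year: {h.birth_year or '-'}\n"
        f"Weight: {_fmt(h.weight)} kg  Height: {_fmt(h.height)} cm  "
        f"BMI: {_fmt(h.bmi)} kg/m2  BSA: {_fmt(h.bsa)} m2\n")
    if h.acquired_at:
        out.write(f"Acquired: {h.acquired_at}\n")

    heading("Measured and derived parameters")
    rows = [("Parameter", "Unit", "Rest", "Peak", "Dynamics (%)")]
    for v in report.values:
        label = v.label + (" [manual]" if v.manual else "")
        rows.append((label, v.unit, _fmt(v.rest), _fmt(v.peak), _fmt(v.dynamics)))
    _write_table(out, rows, md)

    heading("Criteria grid")
    rows = [("Criterion", "Rest", "Peak")]
    rows += [(g.criterion, g.rest, g.peak) for g in report.grid]
    _write_table(out, rows, md)

    heading("Conclusions")
    if report.insufficient_data:
        out.write("Insufficient data for rule-based assessment.\n")
    for line in report.conclusions:
        out.write(f"- {line}\n" if md else f"{line}\n")
    if report.labels:
        out.write("\nDiagnostic statements: " + "; ".join(report.labels) + "\n")
    if report.abnormal_flags:
        out.write("Abnormal parameters: " + ", ".join(report.abnormal_flags) + "\n")
    for c in report.conflicts:
        out.write(f"Note: {c}\n")

    heading("Rule trace")
    for e in report.trace:
        stage = e.stage.value if e.stage else "pair"
        out.write(f"[{e.outcome:>13s}] {e.rule_id} @ {stage}: {e.statement}\n")
        for b in e.bindings:
            mark = {True: "ok", False: "fail", None: "absent"}[b.satisfied]
            tname = f" ({b.threshold_name})" if b.threshold_name else ""
            out.write(f"    {b.param}[{b.bind}] = {_fmt(b.value)} "
                      f"{b.op} {_fmt(b.threshold)}{tname} -> {mark}\n")

    heading("References")
    for ref in report.references:
        out.write(f"- {ref}\n")
    heading("Thresholds in effect")
    for name in sorted(report.thresholds):
        if name != "zero":
            out.write(f"- {name} = {_fmt(report.thresholds[name])}\n")
    return out.getvalue()


def _write_table(out, rows: List[tuple], md: bool) -> None:
    widths = [max(len(str(r[i])) for r in rows) for i in range(len(rows[0]))]
    if md:
        header, *body = rows
        out.write("| " + " | ".join(str(c) for c in header) + " |\n")
        out.write("|" + "|".join("---" for _ in header) + "|\n")
        for r in body:
            out.write("| " + " | ".join(str(c) for c in r) + " |\n")
    else:
        for j, r in enumerate(rows):
            out.write("  ".join(str(c).ljust(w) for c, w in zip(r, widths)).rstrip() + "\n")
            if j == 0:
                out.write("  ".join("-" * w for w in widths) + "\n")


def parse_report_json(payload: str) -> StructuredReport:
    return StructuredReport.model_validate_json(payload)
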