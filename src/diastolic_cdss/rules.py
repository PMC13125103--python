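"""Deterministic IF-THEN inference over derived hemodynamic indices.

Rules are conjunctions of atomic threshold comparisons.  Each atom names a
parameter, a comparator, a threshold (a named entry of
:class:`~diastolic_cdss.model.ThresholdConfig` or a literal), and a *stage
binding*: ``stage`` (the stage currently being evaluated), ``rest``,
``peak``, or ``pair`` (rest-to-peak quantities such as the e' augmentation).
Evaluation is three-valued: a rule *fires* when every atom is satisfied, is
*not fired* when any atom is definitely false, and is *indeterminate* when
no atom is false but some referenced value is absent — absence never
silently counts as normal.

Boundary semantics are strict exactly as written: a value equal to a strict
threshold does not fire (E/e' = 15.0 fails ``E/e' > 15``).

The default rulebase holds the six guideline-derived clinical rules, the
afterload rule, and the per-stage screening/combination criteria that make
up the printed criteria grid of a report.  Fired rules are clustered into
ordered diagnostic statements by an explicit mapping table
(:data:`DEFAULT_CLUSTERS`), not code constants.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field

from .model import (
    DerivedIndexSet,
    EchoMeasurementSet,
    PairIndices,
    Stage,
    StressStudy,
    ThresholdConfig,
)

Comparator = str  # one of "<", ">", "<=", ">="
_COMPARATORS = {"<", ">", "<=", ">="}

GUIDELINE_ASE = "ASE/EACVI 2016 diastolic function recommendations"
GUIDELINE_ESC = "ESC HFpEF consensus"


class ConfigurationError(ValueError):
    """Malformed rule or unknown parameter/threshold name, raised at
    rulebase build time, never during evaluation."""


class Atom(BaseModel):
    model_config = ConfigDict(frozen=True)

    param: str
    op: Comparator
    threshold: Union[str, float]  # ThresholdConfig field name or literal
    bind: str = "stage"  # stage | rest | peak | pair


class Rule(BaseModel):
    model_config = ConfigDict(frozen=True)

    rule_id: str
    scope: str  # rest | peak | pair | either_stage
    atoms: List[Atom]
    statement: str
    guideline_ref: str = GUIDELINE_ASE
    in_grid: bool = False
    criterion_label: Optional[str] = None  # grid row caption


class AtomBinding(BaseModel):
    model_config = ConfigDict(frozen=True)

    param: str
    bind: str
    op: Comparator
    threshold: float
    threshold_name: Optional[str] = None
    value: Optional[float] = None
    satisfied: Optional[bool] = None  # None when the value is absent


class RuleEvaluation(BaseModel):
    model_config = ConfigDict(frozen=True)

    rule_id: str
    statement: str
    stage: Optional[Stage] = None  # None for pair-scoped rules
    outcome: str  # fired | not_fired | indeterminate
    bindings: List[AtomBinding] = Field(default_factory=list)


class DiagnosticConclusion(BaseModel):
    """Ordered clinical statements with their supporting rule trace."""

    statements: List[str] = Field(default_factory=list)
    labels: List[str] = Field(default_factory=list)
    supporting: List[RuleEvaluation] = Field(default_factory=list)
    abnormal_flags: List[str] = Field(default_factory=list)
    conflicts: List[str] = Field(default_factory=list)
    insufficient_data: bool = False


# ---------------------------------------------------------------------------
# default rulebase

def build_default_rulebase(t: Optional[ThresholdConfig] = None) -> List[Rule]:
    """The guideline rulebase: six clinical rules, the afterload rule, and
    the criteria-grid rows (screens and combination criteria).

    Rule ids are stable API.  The borderline flow criterion
    (``vti_borderline_screen``) reads the *peak* VTI at both grid columns:
    it asks whether per-beat outflow distance reaches the normal band under
    load, i.e. flow reserve, not the resting value.
    """
    t = t or ThresholdConfig()
    _validate_thresholds(t)

    def a(param, op, threshold, bind="stage"):
        return Atom(param=param, op=op, threshold=threshold, bind=bind)

    rules = [
        # -- clinical rules -------------------------------------------------
        Rule(rule_id="impaired_reserve", scope="pair",
             atoms=[a("delta_e_prime", "<=", "zero", bind="pair"),
                    a("e_over_eprime", ">", "e_over_eprime_high", bind="peak")],
             statement="Impaired diastolic reserve"),
        Rule(rule_id="rv_dysfunction_load", scope="either_stage",
             atoms=[a("tapse", "<", "tapse_low"),
                    a("pcwp", ">", "pcwp_high")],
             statement="Right ventricular dysfunction under load"),
        Rule(rule_id="svr_vti_low", scope="either_stage",
             atoms=[a("svr", ">", "svr_high"),
                    a("vti", "<", "vti_low")],
             statement="Reduced stroke volume with vasoconstriction"),
        Rule(rule_id="normal_pattern", scope="pair",
             atoms=[a("e_over_eprime", "<=", "e_over_eprime_normal", bind="peak"),
                    a("delta_e_prime", ">", "delta_e_prime_normal", bind="pair")],
             statement="Normal diastolic adaptation to stress"),
        Rule(rule_id="elevated_filling_pressure", scope="either_stage",
             atoms=[a("e_over_eprime", ">", "e_over_eprime_high"),
                    a("tr_vel", ">", "trv_high_bernoulli")],
             statement="Elevated LV filling pressure"),
        Rule(rule_id="postload_low_output", scope="either_stage",
             atoms=[a("pcwp", ">", "pcwp_high"),
                    a("co", "<", "co_low")],
             statement="Post-load elevation with low output"),
        Rule(rule_id="afterload_low_sv", scope="either_stage",
             atoms=[a("pcwp", ">", "pcwp_high"),
                    a("vti", "<", "vti_low")],
             statement="Elevated afterload with low stroke volume"),
        Rule(rule_id="myocardial_stiffness", scope="either_stage",
             atoms=[a("lvsi", ">", "lvsi_high"),
                    a("e_over_eprime", ">", "e_over_eprime_high")],
             statement="Signs of myocardial stiffness",
             guideline_ref="package convention (stiffness index)"),
        # -- criteria grid --------------------------------------------------
        Rule(rule_id="eeprime_high_screen", scope="either_stage", in_grid=True,
             atoms=[a("e_over_eprime", ">", "e_over_eprime_high")],
             statement="Elevated E/e' ratio",
             criterion_label="E/e' > 15"),
        Rule(rule_id="tapse_low_screen", scope="either_stage", in_grid=True,
             atoms=[a("tapse", "<", "tapse_low")],
             statement="Reduced TAPSE",
             criterion_label="TAPSE < 17 mm"),
        Rule(rule_id="vti_low_screen", scope="either_stage", in_grid=True,
             atoms=[a("vti", "<", "vti_low")],
             statement="Reduced LVOT VTI",
             criterion_label="VTI < 18 cm"),
        Rule(rule_id="vti_borderline_screen", scope="either_stage", in_grid=True,
             atoms=[a("vti", "<", "vti_borderline", bind="peak")],
             statement="Borderline LVOT VTI under load",
             criterion_label="VTI < 22 cm"),
        Rule(rule_id="pcwp_high_screen", scope="either_stage", in_grid=True,
             atoms=[a("pcwp", ">", "pcwp_high")],
             statement="Elevated estimated PCWP",
             criterion_label="PCWP > 12 mmHg"),
        Rule(rule_id="hfpef_combo", scope="either_stage", in_grid=True,
             atoms=[a("e_over_eprime", ">", "e_over_eprime_high"),
                    a("delta_e_prime", "<=", "zero", bind="pair"),
                    a("tr_vel", ">", "trv_high_combo")],
             statement="HFpEF criteria combination met",
             guideline_ref=GUIDELINE_ESC,
             criterion_label="E/e' > 15 + Δe' = 0 + TR > 3 m/s"),
        Rule(rule_id="lavi_high_screen", scope="either_stage", in_grid=True,
             atoms=[a("lavi", ">", "lavi_high")],
             statement="Left atrial enlargement",
             criterion_label="LAVi > 34 mL/m²"),
        Rule(rule_id="svr_eeprime_combo", scope="either_stage", in_grid=True,
             atoms=[a("svr", ">", "svr_high"),
                    a("e_over_eprime", ">", "e_over_eprime_high")],
             statement="Elevated vascular resistance with elevated filling pressure",
             criterion_label="SVR > 1,200 + E/e' > 15"),
        Rule(rule_id="fp_preserved_co_ef", scope="either_stage", in_grid=True,
             atoms=[a("pcwp", ">", "pcwp_high"),
                    a("ef", ">=", "ef_preserved"),
                    a("co", ">=", "co_low")],
             statement="Elevated filling pressure despite preserved CO and EF",
             guideline_ref=GUIDELINE_ESC,
             criterion_label="Elevated filling pressure despite preserved CO and EF"),
        Rule(rule_id="resting_svr_high", scope="either_stage", in_grid=True,
             atoms=[a("svr", ">", "svr_high", bind="rest"),
                    a("co", ">=", "co_low"),
                    a("ef", ">=", "ef_preserved")],
             statement="Elevated resting SVR with normal CO and EF",
             criterion_label="Elevated resting SVR with normal CO and EF"),
    ]
    for rule in rules:
        _validate_rule(rule, t)
    return rules


#: parameters a rule predicate may reference, per binding class
_PAIR_PARAMS = {"delta_e_prime", "dri"}


def _stage_params() -> set:
    from .calc import DISPLAY_DECIMALS  # single vocabulary source

    names = set(DerivedIndexSet.model_fields) | set(EchoMeasurementSet.model_fields)
    names |= set(DISPLAY_DECIMALS)
    names -= {"stage", "manual", "overrides"}
    return names


def _validate_rule(rule: Rule, t: ThresholdConfig) -> None:
    if rule.scope not in {"rest", "peak", "pair", "either_stage"}:
        raise ConfigurationError(f"{rule.rule_id}: unknown scope {rule.scope!r}")
    stage_params = _stage_params()
    for atom in rule.atoms:
        if atom.op not in _COMPARATORS:
            raise ConfigurationError(f"{rule.rule_id}: bad comparator {atom.op!r}")
        if atom.bind not in {"stage", "rest", "peak", "pair"}:
            raise ConfigurationError(f"{rule.rule_id}: bad binding {atom.bind!r}")
        if atom.bind == "pair":
            if atom.param not in _PAIR_PARAMS:
                raise ConfigurationError(
                    f"{rule.rule_id}: {atom.param!r} is not a pair-level parameter")
        elif atom.param not in stage_params:
            raise ConfigurationError(
                f"{rule.rule_id}: unknown parameter {atom.param!r}")
        if isinstance(atom.threshold, str) and atom.threshold not in ThresholdConfig.model_fields:
            raise ConfigurationError(
                f"{rule.rule_id}: unknown threshold name {atom.threshold!r}")


def _validate_thresholds(t: ThresholdConfig) -> None:
    for name, value in t.model_dump().items():
        if name != "zero" and value <= 0:
            raise ConfigurationError(f"threshold {name} must be positive")


# ---------------------------------------------------------------------------
# evaluation

class _Context:
    """Parameter lookup over one stage's measurements + derived indices,
    plus the pair-level values."""

    def __init__(self, m: EchoMeasurementSet, d: DerivedIndexSet):
        self.m, self.d = m, d

    def get(self, param: str) -> Optional[float]:
        if param in DerivedIndexSet.model_fields:
            v = getattr(self.d, param)
            if v is not None:
                return v
        if param in EchoMeasurementSet.model_fields and param != "overrides":
            return getattr(self.m, param)
        return None


def _resolve_threshold(atom: Atom, t: ThresholdConfig) -> float:
    if isinstance(atom.threshold, str):
        return float(getattr(t, atom.threshold))
    return float(atom.threshold)


def _compare(value: float, op: Comparator, threshold: float) -> bool:
    if op == "<":
        return value < threshold
    if op == ">":
        return value > threshold
    if op == "<=":
        return value <= threshold
    return value >= threshold


def evaluate_rule(
    rule: Rule,
    thresholds: ThresholdConfig,
    rest_ctx: _Context,
    peak_ctx: _Context,
    pair: PairIndices,
) -> List[RuleEvaluation]:
    """Evaluate one rule at every applicable stage (pure function).

    Three-valued outcome: any false atom -> ``not_fired``; otherwise any
    absent value -> ``indeterminate``; otherwise ``fired``.
    """
    if rule.scope == "either_stage":
        stages: Sequence[Optional[Stage]] = (Stage.rest, Stage.peak)
    elif rule.scope == "pair":
        stages = (None,)
    else:
        stages = (Stage(rule.scope),)

    def lookup(atom: Atom, stage: Optional[Stage]) -> Optional[float]:
        bind = atom.bind
        if bind == "pair" or atom.param in _PAIR_PARAMS:
            return getattr(pair, atom.param)
        if bind == "stage":
            # pair-scoped rules read stage parameters at peak: the loaded
            # state is the diagnostic one
            bind = (stage or Stage.peak).value
        return (rest_ctx if bind == "rest" else peak_ctx).get(atom.param)

    evaluations = []
    for stage in stages:
        bindings = []
        any_false = False
        any_absent = False
        for atom in rule.atoms:
            threshold = _resolve_threshold(atom, thresholds)
            value = lookup(atom, stage)
            satisfied = None if value is None else _compare(value, atom.op, threshold)
            any_false |= satisfied is False
            any_absent |= satisfied is None
            bindings.append(AtomBinding(
                param=atom.param, bind=atom.bind, op=atom.op,
                threshold=threshold,
                threshold_name=atom.threshold if isinstance(atom.threshold, str) else None,
                value=value, satisfied=satisfied))
        outcome = ("not_fired" if any_false
                   else "indeterminate" if any_absent
                   else "fired")
        evaluations.append(RuleEvaluation(
            rule_id=rule.rule_id, statement=rule.statement, stage=stage,
            outcome=outcome, bindings=bindings))
    return evaluations


def evaluate_study(
    rules: Sequence[Rule],
    s: StressStudy,
    thresholds: Optional[ThresholdConfig] = None,
    derived=None,
) -> List[RuleEvaluation]:
    """Evaluate every rule against a study; order is deterministic
    (rulebase order, rest before peak).  ``derived`` may carry a
    precomputed ``(rest, peak, pair)`` triple to avoid recomputation."""
    from .calc import derive_all

    thresholds = thresholds or ThresholdConfig()
    for rule in rules:
        _validate_rule(rule, thresholds)
    rest_d, peak_d, pair = derived if derived is not None else derive_all(s)
    rest_ctx = _Context(s.rest, rest_d)
    peak_ctx = _Context(s.peak, peak_d)
    out: List[RuleEvaluation] = []
    for rule in rules:
        out.extend(evaluate_rule(rule, thresholds, rest_ctx, peak_ctx, pair))
    return out


# ---------------------------------------------------------------------------
# statement clustering

class StatementCluster(BaseModel):
    """Maps a set of rule ids to one diagnostic label and (optionally) one
    narrative conclusion line."""

    model_config = ConfigDict(frozen=True)

    name: str
    rule_ids: List[str]
    label: str
    line: Optional[str] = None


#: normal-report narrative, emitted when the normal-pattern rule fires and
#: no pathological cluster is active
NORMAL_LINES = [
    "Normal diastolic adaptation to exercise. No evidence of HFpEF.",
    "Normal left ventricular filling pressure at rest and during exercise.",
    "Preserved diastolic reserve.",
    "Normal myocardial stiffness.",
]
NORMAL_LABEL = "Normal diastolic function under load"

#: pathological clusters in narrative order; label order below follows the
#: diagnostic-statement vocabulary
DEFAULT_CLUSTERS: List[StatementCluster] = [
    StatementCluster(
        name="hfpef", rule_ids=["hfpef_combo", "fp_preserved_co_ef"],
        label="HFpEF likely",
        line="Hemodynamic profile is consistent with HFpEF criteria."),
    StatementCluster(
        name="filling_pressure",
        rule_ids=["elevated_filling_pressure", "pcwp_high_screen"],
        label="Elevated LV filling pressure",
        line="Stress-induced elevation of left ventricular filling pressure."),
    StatementCluster(
        name="reserve", rule_ids=["impaired_reserve"],
        label="Impaired diastolic reserve",
        line="Diastolic reserve, including indexed reserve, is impaired."),
    StatementCluster(
        name="stiffness", rule_ids=["myocardial_stiffness"],
        label="Signs of myocardial stiffness",
        line="Impaired left ventricular filling due to increased myocardial stiffness."),
    StatementCluster(
        name="vascular",
        rule_ids=["svr_vti_low", "afterload_low_sv", "postload_low_output"],
        label="Reduced stroke volume with increased vascular resistance",
        line="Reduced stroke volume with increased systemic vascular resistance."),
    StatementCluster(
        name="rv", rule_ids=["rv_dysfunction_load"],
        label="Right ventricular dysfunction under load",
        line=None),
]

#: label ordering of the diagnostic-statement vocabulary
_LABEL_ORDER = [
    "Impaired diastolic reserve",
    "Signs of myocardial stiffness",
    "HFpEF likely",
    "Reduced stroke volume with increased vascular resistance",
    "Elevated LV filling pressure",
    "Right ventricular dysfunction under load",
    NORMAL_LABEL,
]


def cluster_statements(
    evaluations: Sequence[RuleEvaluation],
    clusters: Optional[Sequence[StatementCluster]] = None,
) -> DiagnosticConclusion:
    """Cluster fired rules into ordered diagnostic statements.

    The normal-pattern rule alone yields the normal narrative; a
    contradictory set (normal pattern plus a pathological cluster)
    suppresses the normal statement and logs the conflict.
    """
    clusters = DEFAULT_CLUSTERS if clusters is None else list(clusters)
    evaluations = list(evaluations)
    if not evaluations or all(e.outcome == "indeterminate" for e in evaluations):
        return DiagnosticConclusion(insufficient_data=True)

    fired = [e for e in evaluations if e.outcome == "fired"]
    fired_ids = {e.rule_id for e in fired}

    active: List[StatementCluster] = [
        c for c in clusters if fired_ids & set(c.rule_ids)
    ]
    supporting = [e for e in fired
                  if any(e.rule_id in c.rule_ids for c in active)]

    statements: List[str] = []
    labels: List[str] = []
    conflicts: List[str] = []

    pathological = [c for c in active if c.label != NORMAL_LABEL]
    normal_fired = "normal_pattern" in fired_ids
    if normal_fired and not pathological:
        statements.extend(NORMAL_LINES)
        labels.append(NORMAL_LABEL)
        supporting.extend(e for e in fired if e.rule_id == "normal_pattern")
    else:
        if normal_fired and pathological:
            conflicts.append(
                "normal-pattern rule fired alongside pathological clusters "
                f"({', '.join(c.name for c in pathological)}); "
                "normal statement suppressed")
        statements.extend(c.line for c in pathological if c.line)
        labels.extend(c.label for c in pathological)

    labels = sorted(set(labels),
                    key=lambda x: (_LABEL_ORDER.index(x)
                                   if x in _LABEL_ORDER else len(_LABEL_ORDER), x))

    flags: List[str] = []
    for e in fired:
        if e.rule_id == "normal_pattern":
            continue
        for b in e.bindings:
            if b.satisfied and b.param not in flags:
                flags.append(b.param)

    return DiagnosticConclusion(
        statements=statements, labels=labels, supporting=supporting,
        abnormal_flags=flags, conflicts=conflicts)


# ---------------------------------------------------------------------------
# rulebase (de)serialization

def rulebase_to_dicts(rules: Sequence[Rule]) -> List[dict]:
    return [r.model_dump() for r in rules]


def rulebase_from_dicts(
    payload: Sequence[dict], thresholds: Optional[ThresholdConfig] = None
) -> List[Rule]:
    rules = [Rule.model_validate(item) for item in payload]
    t = thresholds or ThresholdConfig()
    for rule in rules:
        _validate_rule(rule, t)
    return rules
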