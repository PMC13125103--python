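"""Synthetic stress-study generator for the two hemodynamic phenotypes.

The generator emulates *measurement-level* variability around the two
reference profiles: normal diastolic adaptation (centroid = worked Case A)
and HFpEF with impaired reserve (centroid = worked Case B).  Each
measurement is drawn as a truncated Gaussian around its centroid (default
SD 7% of the centroid magnitude) independently per parameter; only hard
physiological constraints are enforced on top (chamber ordering, the sign
of the rest-to-peak e' change that defines each phenotype, and
minute-distance = VTI x heart-rate consistency).  No attempt is made to
model a full inter-parameter covariance structure, exercise-protocol
physiology over time, or any real cohort beyond its prevalence.

``perturb_observer`` adds independent re-measurement noise, simulating a
second reader for agreement-statistics exercises (ICC, kappa).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .cases import case_a, case_b
from .model import (
    EchoMeasurementSet,
    PLAUSIBILITY_RANGES,
    PatientDemographics,
    Sex,
    Stage,
    StressStudy,
)

NORMAL = "normal_adaptation"
HFPEF = "hfpef_impaired_reserve"

#: default relative SD of measurement draws (fraction of centroid magnitude)
DEFAULT_REL_SD = 0.07

#: source-population demographics used for synthetic patients
AGE_MEAN, AGE_SD, AGE_RANGE = 61.3, 8.7, (42.0, 77.0)
FEMALE_FRACTION = 0.582


class ParamSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    rest_mean: float
    rest_sd: float
    delta_mean: float  # mean rest->peak change
    delta_sd: float


class PhenotypeSpec(BaseModel):
    """Per-parameter rest and rest->peak change distributions plus the
    phenotype's hard constraints."""

    label: str
    params: Dict[str, ParamSpec]
    overrides: Dict[str, Dict[str, ParamSpec]] = Field(default_factory=dict)
    #: minimum e' augmentation (cm/s); draws are clamped to respect it.
    #: Normal adaptation keeps Δe' comfortably above the 1.5 cm/s reserve
    #: threshold; HFpEF pins Δe' at or below zero.
    min_delta_e_prime: Optional[float] = None
    max_delta_e_prime: Optional[float] = None
    weight: float = 75.0
    height: float = 175.0


def _case_spec(study: StressStudy, label: str, rel_sd: float) -> PhenotypeSpec:
    params: Dict[str, ParamSpec] = {}
    for name in EchoMeasurementSet.model_fields:
        if name in ("stage", "overrides", "minute_distance"):
            continue  # minute distance is reconstructed as VTI x HR
        r = getattr(study.rest, name)
        p = getattr(study.peak, name)
        if r is None or p is None:
            continue
        params[name] = ParamSpec(
            rest_mean=float(r), rest_sd=abs(float(r)) * rel_sd,
            delta_mean=float(p) - float(r),
            delta_sd=max(abs(float(p) - float(r)), 0.1 * abs(float(r))) * rel_sd)
    # heart rate from the printed minute distance (MD = VTI x HR)
    hr_r = study.rest.minute_distance / study.rest.vti
    hr_p = study.peak.minute_distance / study.peak.vti
    params["heart_rate"] = ParamSpec(
        rest_mean=hr_r, rest_sd=hr_r * rel_sd,
        delta_mean=hr_p - hr_r, delta_sd=(hr_p - hr_r) * rel_sd)
    overrides = {}
    for stage_name, mset in (("rest", study.rest), ("peak", study.peak)):
        for key, val in mset.overrides.items():
            overrides.setdefault(key, {})[stage_name] = ParamSpec(
                rest_mean=val, rest_sd=abs(val) * rel_sd,
                delta_mean=0.0, delta_sd=0.0)
    return PhenotypeSpec(
        label=label, params=params, overrides=overrides,
        min_delta_e_prime=2.0 if label == NORMAL else None,
        max_delta_e_prime=0.0 if label == HFPEF else None,
        weight=study.demographics.weight, height=study.demographics.height)


def default_phenotype(label: str, rel_sd: float = DEFAULT_REL_SD) -> PhenotypeSpec:
    """Phenotype centred on the corresponding worked case."""
    if label == NORMAL:
        return _case_spec(case_a(), NORMAL, rel_sd)
    if label == HFPEF:
        return _case_spec(case_b(), HFPEF, rel_sd)
    raise ValueError(f"unknown phenotype label {label!r}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sampled truncated Gaussian; zero SD returns the mean
    (clipped) exactly."""
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _bounds(name: str) -> Tuple[float, float]:
    return PLAUSIBILITY_RANGES.get(name, (-np.inf, np.inf))


def generate_study(
    spec: PhenotypeSpec,
    seed: Union[int, np.random.Generator],
    patient_id: str = "synthetic",
) -> StressStudy:
    """Draw one reproducible study from a phenotype.

    With all SDs zero the result equals the phenotype centroid exactly.
    Generated studies always pass ``validate_study`` without errors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    age = int(round(_truncated_normal(rng, AGE_MEAN, AGE_SD, *AGE_RANGE)))
    sex = Sex.female if rng.random() < FEMALE_FRACTION else Sex.male
    rel = DEFAULT_REL_SD if any(p.rest_sd for p in spec.params.values()) else 0.0
    weight = _truncated_normal(rng, spec.weight, spec.weight * rel, 35, 200)
    height = _truncated_normal(rng, spec.height, spec.height * rel * 0.5, 130, 220)

    rest: Dict[str, float] = {}
    peak: Dict[str, float] = {}
    for name, p in sorted(spec.params.items()):
        lo, hi = _bounds(name)
        r = _truncated_normal(rng, p.rest_mean, p.rest_sd, lo, hi)
        d = rng.normal(p.delta_mean, p.delta_sd) if p.delta_sd else p.delta_mean
        rest[name] = r
        peak[name] = float(min(max(r + d, lo), hi))

    # phenotype-defining constraint on the e' response
    if "e_prime" in rest:
        lo, hi = _bounds("e_prime")
        if spec.max_delta_e_prime is not None:
            peak["e_prime"] = min(peak["e_prime"],
                                  rest["e_prime"] + spec.max_delta_e_prime)
        if spec.min_delta_e_prime is not None:
            peak["e_prime"] = min(max(peak["e_prime"],
                                      rest["e_prime"] + spec.min_delta_e_prime), hi)

    # hard chamber-ordering constraints
    for stage_vals in (rest, peak):
        if "lvids" in stage_vals and "lvidd" in stage_vals:
            stage_vals["lvids"] = min(stage_vals["lvids"],
                                      0.95 * stage_vals["lvidd"])
        if "lvesv" in stage_vals and "lvedv" in stage_vals:
            stage_vals["lvesv"] = min(stage_vals["lvesv"],
                                      0.9 * stage_vals["lvedv"])
        if "ivc_min" in stage_vals and "ivc_max" in stage_vals:
            stage_vals["ivc_min"] = min(stage_vals["ivc_min"],
                                        stage_vals["ivc_max"])

    # minute distance kept consistent with VTI and HR
    for stage_vals in (rest, peak):
        if "vti" in stage_vals and "heart_rate" in stage_vals:
            stage_vals["minute_distance"] = (
                stage_vals["vti"] * stage_vals["heart_rate"])

    ovr: Dict[str, Dict[str, float]] = {"rest": {}, "peak": {}}
    for key, stage_specs in sorted(spec.overrides.items()):
        for stage_name, p in sorted(stage_specs.items()):
            ovr[stage_name][key] = _truncated_normal(
                rng, p.rest_mean, p.rest_sd, 0.0, np.inf)

    return StressStudy(
        demographics=PatientDemographics(
            patient_id=patient_id, age=age, sex=sex,
            weight=round(weight, 1), height=round(height, 1)),
        rest=EchoMeasurementSet(stage=Stage.rest, overrides=ovr["rest"], **rest),
        peak=EchoMeasurementSet(stage=Stage.peak, overrides=ovr["peak"], **peak),
    )


def generate_cohort(
    n: int,
    prevalence: float,
    seed: int,
    rel_sd: float = DEFAULT_REL_SD,
) -> List[Tuple[StressStudy, int]]:
    """Generate ``n`` labelled studies; each is HFpEF with probability
    ``prevalence`` (label 1) else normal adaptation (label 0)."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    specs = {0: default_phenotype(NORMAL, rel_sd),
             1: default_phenotype(HFPEF, rel_sd)}
    out: List[Tuple[StressStudy, int]] = []
    for i in range(n):
        label = int(rng.random() < prevalence)
        study = generate_study(specs[label], rng, patient_id=f"syn-{i:04d}")
        out.append((study, label))
    return out


def perturb_observer(
    study: StressStudy,
    noise: Union[float, Dict[str, float]],
    seed: int,
) -> StressStudy:
    """Simulate an independent second reading: additive truncated-Gaussian
    noise per measurement parameter.

    ``noise`` is either a relative SD applied to every present measurement
    or a mapping parameter -> absolute SD (parameters not named are left
    untouched).  Zero noise returns an identical study.
    """
    rng = np.random.default_rng(seed)
    copy = study.model_copy(deep=True)
    for mset in (copy.rest, copy.peak):
        for name in sorted(EchoMeasurementSet.model_fields):
            if name in ("stage", "overrides"):
                continue
            value = getattr(mset, name)
            if value is None:
                continue
            if isinstance(noise, dict):
                sd = noise.get(name, 0.0)
            else:
                sd = abs(value) * noise
            if sd > 0:
                lo, hi = _bounds(name)
                setattr(mset, name, _truncated_normal(rng, value, sd, lo, hi))
    return copy
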