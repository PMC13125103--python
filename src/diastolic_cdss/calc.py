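"""Calculation engine: derived hemodynamic indices at full precision.

Conventions that matter for reproducing clinical worksheets:

* Body surface area uses Du Bois (0.007184 * W^0.425 * H^0.725).
* Every indexed quantity divides by the BSA *rounded to 2 decimals* — the
  figure a sonographer reads off the worksheet header — while flow uses the
  unrounded LVOT cross-sectional area.
* PCWP is estimated from the E/e' ratio by the linear mapping
  ``1.24 * E/e' + 1.9`` (Nagueh).  The wedge-to-flow ratio ``(E/e')/SV`` is
  computed as well, under its own name (``pcwr_ratio``), and never
  substituted for the pressure estimate.
* Heart rate is recovered as minute_distance / VTI when not entered
  directly (MD = VTI x HR).
* Manual-entry overrides on the measurement set replace the computed value
  for that index and are listed in ``DerivedIndexSet.manual``.

A separate presentation layer (:func:`present`, :func:`presentation_view`)
rounds half-away-from-zero to per-parameter display precision and computes
the dynamics column from the *rounded* stage values, the convention used on
printed reports.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Tuple

from .model import (
    DerivedIndexSet,
    EchoMeasurementSet,
    PairIndices,
    PatientDemographics,
    Stage,
    StressStudy,
)


class DomainError(ValueError):
    """A computation was requested on physically impossible inputs."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3), as clinical
    worksheets do, rather than banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def compute_body_metrics(d: PatientDemographics) -> Tuple[float, float]:
    """Return (BMI kg/m^2, BSA m^2 by Du Bois)."""
    if d.weight <= 0 or d.height <= 0:
        raise DomainError("weight/height", "must be strictly positive")
    bmi = d.weight / (d.height / 100.0) ** 2
    bsa = 0.007184 * d.weight**0.425 * d.height**0.725
    return bmi, bsa


def _bsa2(bsa: float) -> float:
    """BSA as printed on the worksheet header (2 decimals); denominator for
    all indexed quantities."""
    return round_half_away(bsa, 2)


def compute_lv_geometry(m: EchoMeasurementSet, bsa: float) -> Dict[str, Optional[float]]:
    """Chamber geometry block: EF, SF, RWT, LV mass (ASE-corrected cube
    formula) and the BSA-indexed variants."""
    out: Dict[str, Optional[float]] = {}
    b2 = _bsa2(bsa)

    if m.lvedv is not None and m.lvesv is not None:
        if m.lvedv <= m.lvesv:
            raise DomainError("lvedv", "LVEDV must exceed LVESV")
        out["ef"] = (m.lvedv - m.lvesv) / m.lvedv * 100.0
    if m.lvidd is not None and m.lvids is not None and m.lvidd > 0:
        out["sf"] = (m.lvidd - m.lvids) / m.lvidd * 100.0
    if m.pw is not None and m.lvidd is not None and m.lvidd > 0:
        out["rwt"] = 2.0 * m.pw / m.lvidd
    if m.ivs is not None and m.lvidd is not None and m.pw is not None:
        out["lvmm"] = 0.8 * 1.04 * ((m.ivs + m.lvidd + m.pw) ** 3 - m.lvidd**3) + 0.6

    if m.la_diam is not None:
        out["ila"] = m.la_diam / b2
    if m.lvedv is not None:
        out["edvi"] = m.lvedv / b2
    if m.lvesv is not None:
        out["esvi"] = m.lvesv / b2
    if out.get("lvmm") is not None:
        out["ilvmm"] = out["lvmm"] / b2
    if m.lav is not None:
        out["lavi"] = m.lav / b2
    return out


def compute_flow(m: EchoMeasurementSet, bsa: float) -> Dict[str, Optional[float]]:
    """Flow block: LVOT area, stroke volume, heart rate, minute distance,
    cardiac output/index.  SV uses the unrounded LVOT area."""
    out: Dict[str, Optional[float]] = {}
    b2 = _bsa2(bsa)

    if m.lvot_diam is not None:
        out["csa_lvot"] = math.pi * (m.lvot_diam / 2.0) ** 2
    if out.get("csa_lvot") is not None and m.vti is not None:
        out["sv"] = out["csa_lvot"] * m.vti
        out["isv"] = out["sv"] / b2

    hr: Optional[float] = m.heart_rate
    if hr is None and m.minute_distance is not None and m.vti:
        hr = m.minute_distance / m.vti
    out["hr"] = hr
    if hr is not None and m.vti is not None:
        out["md"] = m.vti * hr
    elif m.minute_distance is not None:
        out["md"] = m.minute_distance
    if out.get("sv") is not None and hr is not None:
        out["co"] = out["sv"] * hr / 1000.0  # mL/min -> L/min
        out["ci"] = out["co"] / b2
    return out


def compute_diastolic(
    m: EchoMeasurementSet,
    lvedv: Optional[float] = None,
    sv: Optional[float] = None,
) -> Dict[str, Optional[float]]:
    """Diastolic block: E/A, E/e', the linear PCWP estimate, the
    (E/e')/SV ratio, and the stiffness index (E/e')/LVEDV."""
    out: Dict[str, Optional[float]] = {}
    if m.e_wave is not None and m.a_wave is not None:
        if m.a_wave == 0:
            raise DomainError("a_wave", "zero denominator in E/A")
        out["e_over_a"] = m.e_wave / m.a_wave
    if m.e_wave is not None and m.e_prime is not None:
        if m.e_prime == 0:
            raise DomainError("e_prime", "zero denominator in E/e'")
        ratio = m.e_wave / m.e_prime
        out["e_over_eprime"] = ratio
        out["pcwp"] = 1.24 * ratio + 1.9
        if sv:
            out["pcwr_ratio"] = ratio / sv
        if lvedv:
            out["lvsi"] = ratio / lvedv
    return out


def compute_right_heart(m: EchoMeasurementSet) -> Dict[str, Optional[float]]:
    """Right-heart block: TR/MR gradients (simplified Bernoulli 4v^2), IVC
    collapsibility and the ASE 3/8/15 mmHg right-atrial-pressure rule."""
    out: Dict[str, Optional[float]] = {}
    if m.tr_vel is not None:
        out["trpg"] = 4.0 * m.tr_vel**2
    if m.mr_vel is not None:
        out["mrpg"] = 4.0 * m.mr_vel**2
    if m.ivc_max is not None and m.ivc_min is not None:
        if m.ivc_max == 0:
            raise DomainError("ivc_max", "zero IVC diameter")
        out["ivc_ci"] = (m.ivc_max - m.ivc_min) / m.ivc_max * 100.0
        ci = out["ivc_ci"]
        if m.ivc_max <= 21.0 and ci > 50.0:
            out["rap"] = 3.0
        elif m.ivc_max > 21.0 and ci < 50.0:
            out["rap"] = 15.0
        else:
            out["rap"] = 8.0
    return out


def compute_vascular(
    m: EchoMeasurementSet,
    co: Optional[float],
    rap: Optional[float],
) -> Dict[str, Optional[float]]:
    """MAP from cuff pressures and systemic vascular resistance
    (MAP - RAP)/CO * 80."""
    out: Dict[str, Optional[float]] = {}
    if m.sbp is not None and m.dbp is not None:
        out["map"] = m.dbp + (m.sbp - m.dbp) / 3.0
        if co is not None and rap is not None:
            if co == 0:
                raise DomainError("co", "zero cardiac output in SVR")
            out["svr"] = (out["map"] - rap) / co * 80.0
    return out


def derive_stage(m: EchoMeasurementSet, demo: PatientDemographics) -> DerivedIndexSet:
    """Compose every per-stage block into one :class:`DerivedIndexSet`,
    then apply manual-entry overrides."""
    bmi, bsa = compute_body_metrics(demo)
    values: Dict[str, Optional[float]] = {"bmi": bmi, "bsa": bsa}
    values.update(compute_lv_geometry(m, bsa))
    values.update(compute_flow(m, bsa))
    values.update(compute_diastolic(m, lvedv=m.lvedv, sv=values.get("sv")))
    values.update(compute_right_heart(m))
    values.update(compute_vascular(m, values.get("co"), values.get("rap")))

    manual = []
    b2 = _bsa2(bsa)
    for key, val in m.overrides.items():
        values[key] = val
        manual.append(key)
        # keep the indexed companion consistent with a manual main value
        if key == "lvmm":
            values["ilvmm"] = val / b2
        elif key == "lav":
            values["lavi"] = val / b2
    known = set(DerivedIndexSet.model_fields)
    unknown = set(values) - known
    if unknown:
        raise DomainError(",".join(sorted(unknown)), "unknown derived index name")
    return DerivedIndexSet(stage=m.stage, manual=sorted(manual), **values)


#: measurement parameters shared by both stages, eligible for the dynamics
#: column (stage-invariant demographics excluded)
_DYNAMIC_MEASUREMENTS = [
    "ao_diam", "la_diam", "ivs", "pw", "lvidd", "lvids", "lvedv", "lvesv",
    "rv_diam", "lvot_diam", "vti", "e_wave", "a_wave", "e_prime", "a_prime",
    "ivc_max", "ivc_min", "tr_vel", "mr_vel", "tapse", "lav",
]
_DYNAMIC_DERIVED = [
    "ila", "edvi", "esvi", "ef", "sf", "rwt", "lvmm", "ilvmm", "csa_lvot",
    "sv", "isv", "hr", "co", "ci", "md", "e_over_a", "e_over_eprime",
    "trpg", "mrpg", "ivc_ci", "svr", "pcwp", "lavi", "lvsi",
]


def compute_pair_indices(
    rest: DerivedIndexSet,
    peak: DerivedIndexSet,
    rest_m: EchoMeasurementSet,
    peak_m: EchoMeasurementSet,
    dri_formula=None,
) -> PairIndices:
    """Rest-to-peak indices at full precision.

    ``delta_e_prime`` is the e' augmentation (peak - rest, cm/s), the
    diastolic-reserve marker.  ``dynamics`` holds the percent change of
    every shared parameter whose rest value is nonzero.  The diastolic
    reserve index slot is filled only when a ``dri_formula`` callable is
    supplied (none ships by default; no rule depends on it).
    """
    delta = None
    if rest_m.e_prime is not None and peak_m.e_prime is not None:
        delta = peak_m.e_prime - rest_m.e_prime

    dynamics: Dict[str, float] = {}
    for name in _DYNAMIC_MEASUREMENTS:
        r, p = getattr(rest_m, name), getattr(peak_m, name)
        if r is not None and p is not None and r != 0:
            dynamics[name] = (p - r) / r * 100.0
    for name in _DYNAMIC_DERIVED:
        r, p = getattr(rest, name), getattr(peak, name)
        if r is not None and p is not None and r != 0:
            dynamics[name] = (p - r) / r * 100.0

    dri = dri_formula(rest, peak) if dri_formula is not None else None
    return PairIndices(delta_e_prime=delta, dynamics=dynamics, dri=dri)


def derive_all(
    s: StressStudy, dri_formula=None
) -> Tuple[DerivedIndexSet, DerivedIndexSet, PairIndices]:
    """Derive both stages plus pair-level indices.  Deterministic; callers
    should have screened the study with ``validate_study`` first."""
    rest = derive_stage(s.rest, s.demographics)
    peak = derive_stage(s.peak, s.demographics)
    pair = compute_pair_indices(rest, peak, s.rest, s.peak, dri_formula)
    return rest, peak, pair


# ---------------------------------------------------------------------------
# presentation layer

#: display precision (decimals) per parameter, the package's report style
DISPLAY_DECIMALS: Dict[str, int] = {
    "ao_diam": 1, "la_diam": 1, "ila": 1, "ivs": 1, "pw": 1, "lvidd": 1,
    "lvids": 1, "lvedv": 1, "edvi": 1, "lvesv": 1, "esvi": 1, "rv_diam": 1,
    "ef": 1, "sf": 1, "sv": 1, "isv": 1, "lvmm": 1, "ilvmm": 1, "rwt": 2,
    "lvot_diam": 1, "vti": 1, "e_wave": 0, "a_wave": 0, "e_over_a": 1,
    "e_prime": 0, "a_prime": 0, "e_over_eprime": 1, "ivc_max": 0,
    "ivc_min": 0, "ivc_ci": 0, "csa_lvot": 1, "tr_vel": 1, "trpg": 1,
    "mr_vel": 2, "mrpg": 1, "lav": 0, "lavi": 1, "co": 1, "ci": 1, "md": 0,
    "tapse": 0, "dri": 1, "lvsi": 2, "svr": 1, "pcwp": 1, "pcwr_ratio": 3,
    "rap": 0, "map": 1, "hr": 0, "bmi": 2, "bsa": 2,
}


def present(name: str, value: Optional[float]) -> Optional[float]:
    """Round one value to its display precision (half away from zero)."""
    if value is None:
        return None
    return round_half_away(value, DISPLAY_DECIMALS.get(name, 2))


def presentation_view(
    rest: DerivedIndexSet,
    peak: DerivedIndexSet,
    rest_m: EchoMeasurementSet,
    peak_m: EchoMeasurementSet,
) -> Dict[str, Dict[str, Optional[float]]]:
    """Rounded rest/peak values plus a dynamics column computed *from the
    rounded values* (to 1 decimal), so the printed table is self-consistent
    — the convention clinical worksheets use."""
    view: Dict[str, Dict[str, Optional[float]]] = {}
    for name in _DYNAMIC_MEASUREMENTS:
        view[name] = {"rest": present(name, getattr(rest_m, name)),
                      "peak": present(name, getattr(peak_m, name))}
    for name in _DYNAMIC_DERIVED + ["rap", "map", "pcwr_ratio", "dri"]:
        view[name] = {"rest": present(name, getattr(rest, name)),
                      "peak": present(name, getattr(peak, name))}
    for name, cell in view.items():
        r, p = cell["rest"], cell["peak"]
        cell["dynamics"] = (
            round_half_away((p - r) / r * 100.0, 1)
            if r not in (None, 0) and p is not None else None
        )
    return view
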