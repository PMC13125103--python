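"""Built-in worked cases: the two reference stress studies that anchor the
package's phenotypes and its regression fixtures.

Case A is a physiological adaptation to load (preserved diastolic reserve,
e' rising 12 -> 19 cm/s, E/e' falling on exercise).  Case B is HFpEF with
impaired reserve (e' fixed at 6 cm/s, resting E/e' already above 15, TR
velocity above 3 m/s, TAPSE below 17 mm).

Notes on manual-entry values:

* Case A's LV mass (140/145 g) is a manual worksheet entry — it is not
  consistent with the cube formula for the printed wall thicknesses — and
  is therefore supplied through the override channel the data model
  provides for exactly this situation.
* Systemic vascular resistance requires cuff blood pressure, which neither
  case records; Case B's worksheet SVR values (1,228.0 / 755.3) are
  supplied as overrides so the SVR-gated criteria are exercisable.  Case A
  carries no SVR, so SVR-dependent criteria evaluate indeterminate there
  unless an E/e' atom already decides them.
"""

from __future__ import annotations

from .model import (
    EchoMeasurementSet,
    PatientDemographics,
    Sex,
    Stage,
    StressStudy,
)


def case_a() -> StressStudy:
    """Normal diastolic adaptation to exercise."""
    return StressStudy(
        demographics=PatientDemographics(
            patient_id="case-a", birth_year=1980, age=46,
            sex=Sex.unspecified, weight=75, height=175),
        acquired_at="2026-06-03T04:01:21",
        rest=EchoMeasurementSet(
            stage=Stage.rest,
            ao_diam=3.1, la_diam=3.5, ivs=0.9, pw=0.9,
            lvidd=4.8, lvids=3.1, lvedv=105, lvesv=40, rv_diam=2.8,
            lvot_diam=2.1, vti=21, e_wave=72, a_wave=55,
            e_prime=12, a_prime=10, ivc_max=18, ivc_min=8,
            tr_vel=2.2, mr_vel=0.5, tapse=22, lav=45,
            minute_distance=1365,
            overrides={"lvmm": 140.0},
        ),
        peak=EchoMeasurementSet(
            stage=Stage.peak,
            ao_diam=3.2, la_diam=3.7, ivs=1.0, pw=1.0,
            lvidd=5.0, lvids=2.9, lvedv=120, lvesv=35, rv_diam=2.9,
            lvot_diam=2.1, vti=26, e_wave=96, a_wave=70,
            e_prime=19, a_prime=14, ivc_max=19, ivc_min=9,
            tr_vel=2.6, mr_vel=0.5, tapse=28, lav=48,
            minute_distance=3510,
            overrides={"lvmm": 145.0},
        ),
    )


def case_b() -> StressStudy:
    """HFpEF with impaired diastolic reserve."""
    return StressStudy(
        demographics=PatientDemographics(
            patient_id="case-b", birth_year=1980, age=45,
            sex=Sex.unspecified, weight=60, height=160),
        acquired_at="2026-06-03T03:23:21",
        rest=EchoMeasurementSet(
            stage=Stage.rest,
            ao_diam=2.9, la_diam=3.4, ivs=1.0, pw=1.0,
            lvidd=4.1, lvids=2.5, lvedv=74.2, lvesv=22.3, rv_diam=2.9,
            lvot_diam=2.4, vti=20, e_wave=92, a_wave=60,
            e_prime=6, a_prime=22, ivc_max=30, ivc_min=15,
            tr_vel=3.1, mr_vel=0.95, tapse=16, lav=34,
            minute_distance=1200,
            overrides={"svr": 1228.0},
        ),
        peak=EchoMeasurementSet(
            stage=Stage.peak,
            ao_diam=3.0, la_diam=3.8, ivs=1.1, pw=1.1,
            lvidd=4.5, lvids=2.6, lvedv=92.4, lvesv=24.6, rv_diam=3.1,
            lvot_diam=2.6, vti=19, e_wave=121, a_wave=50,
            e_prime=6, a_prime=18, ivc_max=36, ivc_min=18,
            tr_vel=3.5, mr_vel=0.9, tapse=15, lav=36,
            minute_distance=2660,
            overrides={"svr": 755.3},
        ),
    )
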