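"""Calculation-engine unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diastolic_cdss import (
    EchoMeasurementSet,
    PatientDemographics,
    Stage,
    compute_body_metrics,
    compute_pair_indices,
    derive_all,
    derive_stage,
    round_half_away,
)
from diastolic_cdss.calc import (
    DomainError,
    compute_diastolic,
    compute_flow,
    compute_lv_geometry,
    compute_right_heart,
    compute_vascular,
)


@pytest.mark.parametrize(
    "weight,height,bmi,bsa",
    [
        (75, 175, 24.49, 1.90),  # reference case A header
        (60, 160, 23.44, 1.62),  # reference case B header
        (100, 100, 100.0, None),  # closed form: BMI = w/(h/100)^2
    ],
)
def test_body_metrics(weight, height, bmi, bsa):
    got_bmi, got_bsa = compute_body_metrics(
        PatientDemographics(weight=weight, height=height))
    assert got_bmi == pytest.approx(bmi, abs=0.005)
    if bsa is not None:
        assert round_half_away(got_bsa, 2) == bsa


def test_body_metrics_rejects_nonpositive():
    with pytest.raises(Exception):
        compute_body_metrics(PatientDemographics(weight=-1, height=170))


def test_mosteller_would_fail_case_b():
    # the Du Bois choice is load-bearing: Mosteller rounds to 1.63, not 1.62
    mosteller = math.sqrt(60 * 160 / 3600)
    assert round_half_away(mosteller, 2) != 1.62


class TestLVGeometry:
    def test_case_b_mass_cube_formula(self, study_b, derived_b):
        rest, peak, _ = derived_b
        assert round_half_away(rest.lvmm, 1) == 132.1
        assert round_half_away(peak.lvmm, 1) == 175.0

    def test_case_a_ef_rounds_to_62(self, derived_a):
        rest, _, _ = derived_a
        assert round_half_away(rest.ef, 0) == 62

    def test_mass_formula_additive_constant(self):
        m = EchoMeasurementSet(stage=Stage.rest, ivs=1e-12, pw=1e-12, lvidd=4.0)
        geo = compute_lv_geometry(m, bsa=1.9)
        assert geo["lvmm"] == pytest.approx(0.6, abs=1e-6)

    def test_volume_order_is_domain_error(self):
        m = EchoMeasurementSet(stage=Stage.rest, lvedv=40, lvesv=50)
        with pytest.raises(DomainError):
            compute_lv_geometry(m, bsa=1.9)

    def test_indexing_divides_by_two_decimal_bsa(self):
        # 105 / 1.90 = 55.26 (printed 55.3); 105 / 1.9031 = 55.17 would
        # round to 55.2 — the rounded-BSA denominator is observable
        m = EchoMeasurementSet(stage=Stage.rest, lvedv=105)
        geo = compute_lv_geometry(m, bsa=1.9031365319240374)
        assert round_half_away(geo["edvi"], 1) == 55.3


class TestFlow:
    @pytest.mark.parametrize(
        "lvot,vti,md,sv,hr,co",
        [
            (2.1, 21, 1365, 72.7, 65, 4.7),
            (2.6, 19, 2660, 100.9, 140, 14.1),
        ],
    )
    def test_reference_flow_values(self, lvot, vti, md, sv, hr, co):
        m = EchoMeasurementSet(stage=Stage.rest, lvot_diam=lvot, vti=vti,
                               minute_distance=md)
        flow = compute_flow(m, bsa=1.9)
        assert round_half_away(flow["sv"], 1) == sv
        assert flow["hr"] == pytest.approx(hr)
        assert round_half_away(flow["co"], 1) == co

    def test_sv_uses_unrounded_lvot_area(self):
        m = EchoMeasurementSet(stage=Stage.rest, lvot_diam=2.1, vti=21,
                               minute_distance=1365)
        flow = compute_flow(m, bsa=1.9)
        # rounded CSA (3.5) x 21 = 73.5 would be wrong; unrounded gives 72.7
        assert flow["sv"] == pytest.approx(math.pi * 1.05**2 * 21)

    def test_sv_linearity_in_vti(self):
        base = EchoMeasurementSet(stage=Stage.rest, lvot_diam=2.0, vti=15,
                                  heart_rate=70)
        doubled = base.model_copy(update={"vti": 30.0})
        f1, f2 = compute_flow(base, 1.8), compute_flow(doubled, 1.8)
        assert f2["sv"] == pytest.approx(2 * f1["sv"])
        assert f2["co"] == pytest.approx(2 * f1["co"])

    def test_absent_rate_propagates_absence(self):
        m = EchoMeasurementSet(stage=Stage.rest, lvot_diam=2.0, vti=15)
        flow = compute_flow(m, bsa=1.8)
        assert flow.get("co") is None and flow.get("hr") is None
        assert flow["sv"] is not None


class TestDiastolic:
    @pytest.mark.parametrize(
        "e,eprime,pcwp",
        [(92, 6, 20.9), (96, 19, 8.2), (72, 12, 9.3), (121, 6, 26.9)],
    )
    def test_linear_pcwp_estimator(self, e, eprime, pcwp):
        m = EchoMeasurementSet(stage=Stage.rest, e_wave=e, e_prime=eprime)
        out = compute_diastolic(m)
        assert round_half_away(out["pcwp"], 1) == pcwp

    def test_stiffness_index_case_b(self):
        m = EchoMeasurementSet(stage=Stage.rest, e_wave=92, e_prime=6)
        out = compute_diastolic(m, lvedv=74.2)
        assert round_half_away(out["lvsi"], 2) == 0.21

    def test_wedge_ratio_reported_separately(self):
        m = EchoMeasurementSet(stage=Stage.rest, e_wave=92, e_prime=6)
        out = compute_diastolic(m, sv=90.5)
        assert out["pcwr_ratio"] == pytest.approx((92 / 6) / 90.5)
        assert out["pcwp"] != pytest.approx(out["pcwr_ratio"])

    def test_zero_denominator_is_domain_error(self):
        m = EchoMeasurementSet(stage=Stage.rest, e_wave=92, e_prime=0.0)
        with pytest.raises(DomainError):
            compute_diastolic(m)


class TestRightHeart:
    def test_bernoulli_gradient(self):
        m = EchoMeasurementSet(stage=Stage.rest, tr_vel=3.1)
        assert round_half_away(compute_right_heart(m)["trpg"], 1) == 38.4

    def test_zero_velocity_zero_gradient(self):
        m = EchoMeasurementSet(stage=Stage.rest, tr_vel=1e-9)
        assert compute_right_heart(m)["trpg"] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "ivc_max,ivc_min,ci,rap",
        [
            (30, 15, 50.0, 8.0),   # dilated, intermediate collapse
            (18, 8, 55.6, 3.0),    # small and collapsing -> low RAP
            (25, 20, 20.0, 15.0),  # dilated and plethoric -> high RAP
        ],
    )
    def test_ivc_collapsibility_and_rap_rule(self, ivc_max, ivc_min, ci, rap):
        m = EchoMeasurementSet(stage=Stage.rest, ivc_max=ivc_max,
                               ivc_min=ivc_min)
        out = compute_right_heart(m)
        assert out["ivc_ci"] == pytest.approx(ci, abs=0.05)
        assert out["rap"] == rap


class TestVascular:
    def test_svr_formula(self):
        m = EchoMeasurementSet(stage=Stage.rest, sbp=120, dbp=78.75)
        out = compute_vascular(m, co=4.73, rap=3.0)
        assert out["map"] == pytest.approx(92.5)
        assert out["svr"] == pytest.approx((92.5 - 3) / 4.73 * 80)

    def test_map_equals_rap_gives_zero(self):
        m = EchoMeasurementSet(stage=Stage.rest, sbp=100, dbp=100)
        assert compute_vascular(m, co=5.0, rap=100.0)["svr"] == 0.0

    def test_svr_inverse_in_co(self):
        m = EchoMeasurementSet(stage=Stage.rest, sbp=130, dbp=80)
        one = compute_vascular(m, co=4.0, rap=5.0)["svr"]
        two = compute_vascular(m, co=8.0, rap=5.0)["svr"]
        assert two == pytest.approx(one / 2)

    def test_absent_bp_degrades(self):
        m = EchoMeasurementSet(stage=Stage.rest)
        assert compute_vascular(m, co=5.0, rap=8.0) == {}


class TestPairIndices:
    def test_delta_e_prime(self, study_b, derived_b):
        rest, peak, pair = derived_b
        assert pair.delta_e_prime == 0.0

    def test_dynamics_full_precision(self, derived_b):
        _, _, pair = derived_b
        assert pair.dynamics["e_over_a"] == pytest.approx(
            ((121 / 50) - (92 / 60)) / (92 / 60) * 100)

    def test_equal_stages_give_zero_dynamics(self, study_a):
        s = study_a.model_copy(deep=True)
        data = s.rest.model_dump()
        data["stage"] = Stage.peak
        s.peak = EchoMeasurementSet(**data)
        _, _, pair = derive_all(s)
        assert all(v == pytest.approx(0.0) for v in pair.dynamics.values())


# --- derive_all integration ------------------------------------------------

def _random_measurements(rng, stage):
    return EchoMeasurementSet(
        stage=stage,
        ao_diam=rng.uniform(2, 4), la_diam=rng.uniform(2.5, 5),
        ivs=rng.uniform(0.6, 1.5), pw=rng.uniform(0.6, 1.5),
        lvidd=(lvidd := rng.uniform(3.5, 6.0)),
        lvids=rng.uniform(0.5, 0.8) * lvidd,
        lvedv=(lvedv := rng.uniform(60, 180)),
        lvesv=rng.uniform(0.2, 0.6) * lvedv,
        rv_diam=rng.uniform(2, 4), lvot_diam=rng.uniform(1.8, 2.8),
        vti=rng.uniform(12, 30), e_wave=rng.uniform(40, 140),
        a_wave=rng.uniform(30, 110), e_prime=rng.uniform(4, 20),
        a_prime=rng.uniform(4, 20),
        ivc_max=(ivc := rng.uniform(10, 30)),
        ivc_min=rng.uniform(0.2, 0.9) * ivc,
        tr_vel=rng.uniform(1.5, 4), mr_vel=rng.uniform(0.3, 2),
        tapse=rng.uniform(10, 30), lav=rng.uniform(20, 80),
        heart_rate=rng.uniform(50, 170),
        sbp=rng.uniform(95, 180), dbp=rng.uniform(55, 95),
    )


def _straight_line_reference(m, demo):
    """Independent re-evaluation of every formula, written linearly."""
    bmi = demo.weight / (demo.height / 100) ** 2
    bsa = 0.007184 * demo.weight**0.425 * demo.height**0.725
    b2 = round_half_away(bsa, 2)
    csa = math.pi * (m.lvot_diam / 2) ** 2
    sv = csa * m.vti
    co = sv * m.heart_rate / 1000
    ratio = m.e_wave / m.e_prime
    ivc_ci = (m.ivc_max - m.ivc_min) / m.ivc_max * 100
    if m.ivc_max <= 21 and ivc_ci > 50:
        rap = 3.0
    elif m.ivc_max > 21 and ivc_ci < 50:
        rap = 15.0
    else:
        rap = 8.0
    mean_ap = m.dbp + (m.sbp - m.dbp) / 3
    return {
        "bmi": bmi, "bsa": bsa,
        "ef": (m.lvedv - m.lvesv) / m.lvedv * 100,
        "sf": (m.lvidd - m.lvids) / m.lvidd * 100,
        "rwt": 2 * m.pw / m.lvidd,
        "lvmm": 0.8 * 1.04 * ((m.ivs + m.lvidd + m.pw) ** 3 - m.lvidd**3) + 0.6,
        "ila": m.la_diam / b2, "edvi": m.lvedv / b2, "esvi": m.lvesv / b2,
        "lavi": m.lav / b2, "csa_lvot": csa, "sv": sv, "isv": sv / b2,
        "hr": m.heart_rate, "md": m.vti * m.heart_rate,
        "co": co, "ci": co / b2,
        "e_over_a": m.e_wave / m.a_wave, "e_over_eprime": ratio,
        "pcwp": 1.24 * ratio + 1.9, "pcwr_ratio": ratio / sv,
        "lvsi": ratio / m.lvedv,
        "trpg": 4 * m.tr_vel**2, "mrpg": 4 * m.mr_vel**2,
        "ivc_ci": ivc_ci, "rap": rap, "map": mean_ap,
        "svr": (mean_ap - rap) / co * 80,
    }


def test_oracle_equivalence_on_random_studies():
    """derive_stage agrees with a straight-line re-evaluation of every
    formula to <=1e-9 relative error on 1,000 random valid sets."""
    rng = np.random.default_rng(20260929)
    demo = PatientDemographics(weight=75, height=175)
    for _ in range(1000):
        m = _random_measurements(rng, Stage.rest)
        got = derive_stage(m, demo)
        want = _straight_line_reference(m, demo)
        for key, ref in want.items():
            value = getattr(got, key)
            assert value == pytest.approx(ref, rel=1e-9), key


def test_derive_all_deterministic(study_b):
    a = derive_all(study_b)
    b = derive_all(study_b)
    assert a == b


def test_unit_coherence_co_sv_hr(derived_a, derived_b):
    for rest, peak, _ in (derived_a, derived_b):
        for d in (rest, peak):
            assert d.co == pytest.approx(d.sv * d.hr / 1000, rel=1e-12)


def test_indexed_values_recover_raw(study_b, derived_b):
    rest, _, _ = derived_b
    b2 = round_half_away(rest.bsa, 2)
    assert rest.edvi * b2 == pytest.approx(study_b.rest.lvedv, rel=1e-12)
    assert rest.isv * b2 == pytest.approx(rest.sv, rel=1e-12)


@given(ratio=st.floats(1.0, 30.0), bump=st.floats(0.1, 5.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_pcwp_strictly_increasing_in_ratio(ratio, bump):
    lo = compute_diastolic(EchoMeasurementSet(
        stage=Stage.rest, e_wave=ratio * 6, e_prime=6))["pcwp"]
    hi = compute_diastolic(EchoMeasurementSet(
        stage=Stage.rest, e_wave=(ratio + bump) * 6, e_prime=6))["pcwp"]
    assert hi > lo


@given(v=st.floats(0.5, 5.5), bump=st.floats(0.01, 1.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_trpg_strictly_increasing_in_velocity(v, bump):
    g = lambda vel: compute_right_heart(
        EchoMeasurementSet(stage=Stage.rest, tr_vel=vel))["trpg"]
    assert g(v + bump) > g(v)


@pytest.mark.parametrize("decimals,value,expected", [
    (0, 2.5, 3.0), (0, -2.5, -3.0), (1, 0.05, 0.1), (1, 19.36, 19.4),
    (0, 61.905, 62.0), (2, 0.488, 0.49),
])
def test_round_half_away(decimals, value, expected):
    assert round_half_away(value, decimals) == expected
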