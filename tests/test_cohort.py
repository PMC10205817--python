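"""Synthetic cohort generator: calibration, determinism, suture model."""

import numpy as np
import pytest

from coasim.cohort import (
    GROUP_NAMES,
    TIMEPOINTS_WEEKS,
    CohortConfig,
    StudyGroup,
    cohort_frame,
    coarctation_timecourse,
    generate_material_curve,
    generate_subject,
    group_calibration,
    make_group,
    obstruction_timecourse,
)
from coasim.geometry import compute_obstruction, tangent_modulus
from coasim.measurements import apply_transfer, bernoulli_gradient, summarize_pressure
from coasim.waveform import generate_pressure_waveform
from coasim.windkessel import estimate_tau


class TestStudyGroup:
    def test_wire_severity_bijection(self):
        assert make_group("permanent", "ge20").wire_diameter_mm == 1.6
        assert make_group("dissolvable", "10to20").wire_diameter_mm == 2.0
        assert make_group("rapid", "le10").wire_diameter_mm == 2.6

    def test_mismatched_wire_rejected(self):
        with pytest.raises(ValueError):
            StudyGroup("permanent", 1.6, "le10")

    def test_round_trip_names(self):
        for name in GROUP_NAMES:
            assert StudyGroup.from_name(name).name == name


class TestCoarctationTimecourse:
    def test_permanent_is_constant_wire(self):
        g = make_group("permanent", "ge20")
        for t in (0.0, 1.0, 10.0, 50.0):
            assert coarctation_timecourse(g, t, 5.66) == 1.6

    def test_dissolvable_residual_matches_final_obstruction(self):
        # 47 % residual obstruction: 5.66*sqrt(0.53) = 4.12 mm
        g = make_group("dissolvable", "ge20")
        assert coarctation_timecourse(g, 20.0, 5.66) == pytest.approx(4.12, abs=0.01)

    def test_rapid_long_time_residual(self):
        g = make_group("rapid", "ge20")
        d = coarctation_timecourse(g, 1000.0, 5.66)
        assert compute_obstruction(d, 5.66) == pytest.approx(33.0, abs=0.5)

    def test_reference_below_wire_rejected(self):
        with pytest.raises(ValueError):
            coarctation_timecourse(make_group("permanent", "le10"), 1.0, 2.0)

    def test_control_returns_reference(self):
        assert coarctation_timecourse(make_group(None), 5.0, 4.2) == 4.2


class TestGenerateSubject:
    def test_deterministic_for_fixed_seed(self):
        a = generate_subject("control", 42)
        b = generate_subject("control", 42)
        assert np.array_equal(a.body_weight_kg, b.body_weight_kg)
        assert np.array_equal(a.doppler_peak_velocity_m_s, b.doppler_peak_velocity_m_s)
        assert a.station_diameters == b.station_diameters
        assert np.array_equal(a.catheter_waveforms[0].v, b.catheter_waveforms[0].v)
        assert a.branch_mean_flows_ml_s == b.branch_mean_flows_ml_s

    def test_control_catheter_pressures_near_calibration(self):
        rec = generate_subject("control", 42)
        mbp, pp = summarize_pressure(rec.catheter_waveforms[0])
        assert mbp == pytest.approx(55.7, abs=2.0)
        assert pp == pytest.approx(14.9, abs=2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 7])
    def test_severe_group_doppler_implies_ge20(self, seed):
        rec = generate_subject("coa_ge20", seed)
        v4 = rec.doppler_peak_velocity_m_s[-1]
        implied = apply_transfer(bernoulli_gradient(v4))
        assert implied >= 20.0

    def test_obstruction_matches_calibration_within_1pp(self):
        for name in GROUP_NAMES:
            rec = generate_subject(name, 5)
            cal = group_calibration(name)
            assert np.all(np.abs(rec.obstruction_pct - np.asarray(cal["obstruction"])) < 1.0)

    def test_control_coarctation_equals_reference(self):
        rec = generate_subject("control", 3, CohortConfig(noise_scale=0.0))
        for k in range(4):
            d_coa = rec.station_diameters[k]["coa"][0]
            assert compute_obstruction(d_coa, d_coa) == 0.0
        assert np.all(rec.obstruction_pct == 0)

    def test_severity_monotone_doppler_at_tp1(self):
        for seed in (0, 1, 2):
            v = {
                sev: generate_subject(f"coa_{sev}", seed).doppler_peak_velocity_m_s[0]
                for sev in ("le10", "10to20", "ge20")
            }
            assert v["ge20"] > v["10to20"] > v["le10"]

    def test_record_invariants(self):
        for name in ("control", "dcoa_ge20", "rdcoa_10to20"):
            rec = generate_subject(name, 11)
            rec.validate()
            assert np.all(np.diff(rec.body_weight_kg) > 0)
            for per_tp in rec.station_diameters:
                for dia, sys in per_tp.values():
                    assert sys >= dia > 0

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            generate_subject("coa_le5", 0)


class TestObstructionTimecourse:
    def test_anchored_at_timepoints(self):
        for name in GROUP_NAMES:
            cal = group_calibration(name)
            got = obstruction_timecourse(name, list(TIMEPOINTS_WEEKS))
            assert np.allclose(got, cal["obstruction"])


class TestPressureWaveform:
    def test_realized_mean_and_pulse(self):
        w = generate_pressure_waveform(55.7, 14.9, 220, 0.8, 5)
        mbp, pp = summarize_pressure(w)
        assert mbp == pytest.approx(55.7, rel=0.01)
        assert pp == pytest.approx(14.9, abs=0.15)

    def test_zero_pulse_is_constant(self):
        w = generate_pressure_waveform(60, 0, 220, 0.8, 1)
        assert np.allclose(w.v, 60.0)

    def test_diastolic_log_slope_recovers_tau(self):
        w = generate_pressure_waveform(55.7, 14.9, 220, 0.8, 3)
        assert estimate_tau(w) == pytest.approx(0.8, rel=0.01)

    def test_non_physical_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_pressure_waveform(5.0, 14.9, 220, 0.8, 1)
        with pytest.raises(ValueError):
            generate_pressure_waveform(60, -1, 220, 0.8, 1)


class TestMaterialCurve:
    def test_tangent_hits_target(self):
        curve = generate_material_curve(190.0, 0.11)
        assert tangent_modulus(curve, 0.11) == pytest.approx(190.0, rel=1e-9)

    def test_linear_limit(self):
        curve = generate_material_curve(150.0, 0.2, coef_b=0.0)
        assert tangent_modulus(curve, 0.05) == pytest.approx(150.0, rel=1e-9)

    def test_exponential_example(self):
        # sigma = 100*(exp(5 eps) - 1): tangent at 0.11 is 500*e^0.55
        curve = generate_material_curve(866.61, 0.11, coef_b=5.0)
        assert curve.coef_a == pytest.approx(100.0, rel=1e-3)
        assert tangent_modulus(curve, 0.11) == pytest.approx(500 * np.exp(0.55), rel=1e-3)

    def test_curve_through_origin_and_monotone(self):
        curve = generate_material_curve(300.0, 0.1)
        assert curve.stress_kpa[0] == 0.0
        assert np.all(np.diff(curve.stress_kpa) >= 0)


def test_cohort_frame_schema():
    recs = [generate_subject("control", 1), generate_subject("coa_ge20", 1)]
    df = cohort_frame(recs)
    assert len(df) == 2 * 4 * 6  # subjects x TPs x stations
    assert {"group", "tp", "station", "d_dia_mm", "d_sys_mm"} <= set(df.columns)
    assert (df.d_sys_mm >= df.d_dia_mm).all()
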