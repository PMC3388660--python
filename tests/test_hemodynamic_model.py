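"""Unit and property tests for the patient simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lirsim.hemodynamic_model import (
    PHASE1_RANGES,
    PHASE23_RANGES,
    DoseEvent,
    PatientParams,
    apply_drug,
    baseline_state,
    ledger_residual,
    ppv_from_deficit,
    sample_patient,
    step,
)

DT = 1.0 / 12.0


def run_unmanaged(params, hemorrhage_volume, hemorrhage_rate, total_min,
                  maintenance=0.0):
    """Bleed at a constant rate from t=0, then coast; return the trajectory."""
    state = baseline_state(params)
    bleed_min = hemorrhage_volume / hemorrhage_rate if hemorrhage_rate else 0.0
    states = [state]
    for i in range(int(round(total_min / DT))):
        t = i * DT
        hem = hemorrhage_rate if t < bleed_min - 1e-9 else 0.0
        state = step(state, params, {"hemorrhage_rate": hem,
                                     "crystalloid_rate": maintenance}, DT)
        states.append(state)
    return states


class TestSamplePatient:
    def test_samples_stay_inside_ranges(self, rng):
        for _ in range(200):
            p = sample_patient(PHASE1_RANGES, rng)
            for name, (lo, hi) in PHASE1_RANGES.items():
                assert lo <= getattr(p, name) <= hi
            assert p.blood_volume_base == pytest.approx(p.weight * 70.0)

    def test_degenerate_ranges_give_exact_midpoints(self, rng):
        ranges = {k: (70.0, 70.0) for k in PHASE1_RANGES}
        ranges["lvesv_base"] = (50.0, 50.0)
        ranges["lvedv_base"] = (140.0, 140.0)
        ranges["sbp_base"] = (120.0, 120.0)
        p = sample_patient(ranges, rng)
        assert p.weight == 70.0 and p.hr_base == 70.0 and p.lvedv_base == 140.0

    def test_large_sample_mean_near_range_center(self, rng):
        hrs = [sample_patient(PHASE23_RANGES, rng).hr_base for _ in range(10_000)]
        assert 65.0 <= np.mean(hrs) <= 75.0
        assert abs(np.mean(hrs) - 70.0) < 0.3

    def test_reversed_range_names_the_field(self, rng):
        bad = dict(PHASE1_RANGES, hr_base=(85.0, 55.0))
        with pytest.raises(ValueError, match="hr_base"):
            sample_patient(bad, rng)


class TestBaselineState:
    def test_stroke_volume_and_cardiac_output(self, default_patient):
        s = baseline_state(default_patient)
        assert s.sv == pytest.approx(90.0)
        assert s.co == pytest.approx(6.30)

    def test_map_one_third_pulse_pressure(self, default_patient):
        s = baseline_state(default_patient)
        assert s.map == pytest.approx(75 + (120 - 75) / 3)  # 90 mm Hg

    def test_baseline_is_equilibrium_for_30_minutes(self, default_patient):
        states = run_unmanaged(default_patient, 0.0, 0.0, 30.0)
        first, last = states[0], states[-1]
        for attr in ("hr", "sv", "co", "sbp", "dbp", "map", "ppv_true",
                     "intravascular_volume"):
            assert getattr(last, attr) == pytest.approx(getattr(first, attr), abs=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PatientParams(weight=75, height=67, hr_base=70, sbp_base=120,
                          dbp_base=75, lvedv_base=50, lvesv_base=140,
                          blood_volume_base=5250)


class TestPPVFromDeficit:
    def test_zero_deficit_returns_baseline(self, default_patient):
        assert ppv_from_deficit(0.0, default_patient) == pytest.approx(6.0)

    def test_calibration_anchors_for_default_patient(self, default_patient):
        bv = default_patient.blood_volume_base
        assert ppv_from_deficit(600.0 / bv, default_patient) == pytest.approx(10.0, abs=0.1)
        assert ppv_from_deficit(700.0 / bv, default_patient) == pytest.approx(15.0, abs=0.1)

    def test_monotone_nondecreasing_on_grid(self, default_patient):
        grid = np.linspace(0.0, 1.0, 1000)
        vals = [ppv_from_deficit(f, default_patient) for f in grid]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_input_clamped(self, default_patient):
        assert ppv_from_deficit(-0.5, default_patient) == pytest.approx(6.0)
        assert ppv_from_deficit(2.0, default_patient) == ppv_from_deficit(1.0, default_patient)


class TestStep:
    def test_hemorrhage_ledger_is_rate_times_time(self, default_patient):
        states = run_unmanaged(default_patient, 2000.0, 100.0, 20.0)
        assert states[-1].cumulative_hemorrhage == pytest.approx(2000.0)

    def test_rejects_negative_rates_and_bad_dt(self, default_baseline, default_patient):
        with pytest.raises(ValueError):
            step(default_baseline, default_patient, {"hemorrhage_rate": -1.0}, DT)
        with pytest.raises(ValueError):
            step(default_baseline, default_patient, {}, 0.0)
        with pytest.raises(ValueError):
            step(default_baseline, default_patient, {}, 1.0)

    def test_internal_consistency_identities(self, default_patient):
        states = run_unmanaged(default_patient, 1500.0, 16.7, 120.0, maintenance=3.33)
        for s in states[:: 7 * 12]:
            assert s.co == pytest.approx(s.hr * s.sv / 1000.0, rel=1e-9)
            assert s.map == pytest.approx(s.dbp + (s.sbp - s.dbp) / 3.0, rel=1e-9)
            assert s.ppv_true >= 0 and s.sv >= 0

    def test_dose_response_ordering_in_hemorrhage_volume(self, default_patient):
        finals = []
        for volume in (500.0, 1500.0, 2000.0):
            states = run_unmanaged(default_patient, volume, 100.0, 60.0)
            finals.append(states[-1].co)
        assert finals[0] > finals[1] > finals[2]

    def test_starling_plateau_limits_over_resuscitation(self, default_patient):
        state = baseline_state(default_patient)
        co_vals = [state.co]
        # infuse 3 x 500 ml colloid past euvolemia
        for _ in range(3):
            for _ in range(int(10 / DT)):
                state = step(state, default_patient, {"colloid_rate": 50.0}, DT)
            for _ in range(int(5 / DT)):
                state = step(state, default_patient, {}, DT)
            co_vals.append(state.co)
        for before, after in zip(co_vals, co_vals[1:]):
            assert (after - before) / before < 0.02

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 50), st.floats(0, 30)),
                    min_size=1, max_size=40))
    def test_volume_conservation_ledger_closes(self, schedule):
        params = PatientParams(weight=75.0, height=67.0, hr_base=70.0,
                               sbp_base=120.0, dbp_base=75.0, lvedv_base=140.0,
                               lvesv_base=50.0, blood_volume_base=5250.0)
        state = baseline_state(params)
        for hem, cry, col in schedule:
            for _ in range(6):
                state = step(state, params, {"hemorrhage_rate": hem,
                                             "crystalloid_rate": cry,
                                             "colloid_rate": col}, DT)
                assert abs(ledger_residual(state, params)) < 0.1

    def test_deterministic_trajectories(self, default_patient):
        a = run_unmanaged(default_patient, 2000.0, 100.0, 40.0, maintenance=3.33)
        b = run_unmanaged(default_patient, 2000.0, 100.0, 40.0, maintenance=3.33)
        assert all(x.co == y.co and x.map == y.map and x.ppv_true == y.ppv_true
                   for x, y in zip(a, b))


class TestDrugs:
    def test_phenylephrine_raises_map_over_5_minutes(self, default_patient):
        # moderate shock first: bleed 1,200 ml
        states = run_unmanaged(default_patient, 1200.0, 100.0, 20.0)
        state = states[-1]
        map_before = state.map
        state = apply_drug(state, default_patient, DoseEvent("phenylephrine", 100.0, 20.0))
        maps = []
        for _ in range(int(5 / DT)):
            state = step(state, default_patient, {}, DT)
            maps.append(state.map)
        assert maps[0] > map_before
        assert 4.0 < max(maps) - map_before < 15.0  # ~8-12 mm Hg by design

    def test_zero_dose_is_a_no_op(self, default_baseline, default_patient):
        out = apply_drug(default_baseline, default_patient,
                         DoseEvent("ephedrine", 0.0, 0.0))
        assert out.hr == default_baseline.hr and out.map == default_baseline.map

    def test_repeat_dosing_saturates(self, default_baseline, default_patient):
        one = apply_drug(default_baseline, default_patient,
                         DoseEvent("phenylephrine", 100.0, 0.0))
        two = apply_drug(one, default_patient, DoseEvent("phenylephrine", 100.0, 0.0))
        single = one.map - default_baseline.map
        double = two.map - default_baseline.map
        assert single <= double <= 2 * single

    def test_unknown_drug_rejected(self):
        with pytest.raises(ValueError, match="unknown drug"):
            DoseEvent("dopamine", 5.0, 0.0)

    def test_fentanyl_lowers_heart_rate(self, default_baseline, default_patient):
        out = apply_drug(default_baseline, default_patient,
                         DoseEvent("fentanyl", 50.0, 0.0))
        assert out.hr < default_baseline.hr


class TestDetectionTiming:
    """Hemorrhage-detection ordering: PPV leads CO/MAP/HR changes."""

    def test_ppv_is_the_earliest_indicator_in_massive_bleed(self, default_patient):
        states = run_unmanaged(default_patient, 2000.0, 100.0, 25.0, maintenance=3.33)
        base = states[0]

        def first_time(pred):
            return next((s.t for s in states if pred(s)), math.inf)

        t_ppv = first_time(lambda s: s.ppv_true >= 10.0)
        t_co = first_time(lambda s: s.co <= 0.9 * base.co)
        t_map = first_time(lambda s: s.map <= 0.9 * base.map)
        t_hr = first_time(lambda s: s.hr >= 1.1 * base.hr)
        assert t_ppv < min(t_co, t_map, t_hr)
        assert 5.0 <= t_ppv <= 9.0
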