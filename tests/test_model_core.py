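import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vvcsim.model_core import (
    SimulationError,
    chamber_pressure,
    derivatives,
    elastance_at,
    initial_state,
    simulate,
    valve_flow,
)
from vvcsim.parameters import ChamberParams, CompartmentParams, default_parameters

SYMMETRIC = ChamberParams(e_max=2.0, e_min=0.1, v0=10.0,
                          activation_duration_fraction=0.4,
                          activation_delay=0.1)


class TestElastance:
    def test_outside_window_gives_e_min(self):
        assert elastance_at(0.05, SYMMETRIC, 0.75) == SYMMETRIC.e_min
        assert elastance_at(0.55, SYMMETRIC, 0.75) == SYMMETRIC.e_min

    def test_peak_gives_e_max(self):
        t_act = 0.4 * 0.75
        assert elastance_at(0.1 + 0.5 * t_act, SYMMETRIC, 0.75) == pytest.approx(
            SYMMETRIC.e_max, rel=1e-12)

    def test_symmetric_quarter_point_is_half_activation(self):
        # sin^2(pi/4) = 0.5 for the symmetric squared half-sine
        t_act = 0.4 * 0.75
        e = elastance_at(0.1 + 0.25 * t_act, SYMMETRIC, 0.75)
        assert e == pytest.approx(
            SYMMETRIC.e_min + 0.5 * (SYMMETRIC.e_max - SYMMETRIC.e_min), rel=1e-12)

    def test_rejects_non_finite_and_out_of_cycle(self):
        with pytest.raises(ValueError):
            elastance_at(float("nan"), SYMMETRIC, 0.75)
        with pytest.raises(ValueError):
            elastance_at(0.8, SYMMETRIC, 0.75)

    @given(st.floats(0.0, 0.7499), st.floats(0.05, 0.95))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bounded_and_zero_outside_window(self, t, rise):
        ch = replace(SYMMETRIC, activation_rise_fraction=rise)
        e = elastance_at(t, ch, 0.75)
        assert ch.e_min <= e <= ch.e_max
        t_act = ch.activation_duration_fraction * 0.75
        if not (ch.activation_delay <= t <= ch.activation_delay + t_act):
            assert e == ch.e_min


class TestChamberPressureAndValves:
    def test_unstressed_volume_gives_zero_pressure(self):
        assert chamber_pressure(10.0, 2.0, 10.0) == 0.0

    def test_arithmetic(self):
        assert chamber_pressure(60.0, 2.0, 10.0) == 100.0

    @given(st.floats(-50, 300), st.floats(-50, 300), st.floats(0.01, 5.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pressure_linear_in_stressed_volume(self, v1, v2, e):
        v0 = 10.0
        p1 = chamber_pressure(v1, e, v0)
        p2 = chamber_pressure(v2, e, v0)
        assert p1 + p2 == pytest.approx(
            chamber_pressure(v1 + v2 - v0, e, v0), rel=1e-9, abs=1e-9)

    def test_valve_closed_open_and_continuity(self):
        assert valve_flow(80.0, 120.0, 0.01) == 0.0
        assert valve_flow(120.0, 80.0, 0.01) == pytest.approx(4000.0)
        assert valve_flow(100.0, 100.0, 0.01) == 0.0

    def test_valve_never_negative(self):
        for dp in np.linspace(-50, 50, 21):
            assert valve_flow(100.0 + dp, 100.0, 0.02) >= 0.0

    def test_valve_rejects_nonpositive_resistance(self):
        with pytest.raises(ValueError):
            valve_flow(1.0, 0.0, 0.0)


class TestDerivatives:
    def test_volume_derivatives_sum_to_zero(self, base_params):
        y = initial_state(base_params)
        y[14] = 250.0  # mid-ejection aortic flow
        for t in (0.0, 0.2, 0.45, 0.7):
            dy = derivatives(y, t, base_params)
            assert abs(dy[:14].sum()) < 1e-9

    def test_uniform_pressure_equilibrium_is_stationary(self, base_params):
        # all compartments at 10 mmHg, chambers inactive (t = 0.70 is outside
        # every activation window), valves see zero gradients
        p = base_params
        target = 10.0
        y = np.empty(15)
        for k, ch in enumerate((p.la, p.lv, p.ra, p.rv)):
            y[k] = ch.v0 + target / ch.e_min
        for j, comp in enumerate(p.compartments):
            y[4 + j] = comp.v_unstressed + target * comp.compliance
        y[14] = 0.0
        dy = derivatives(y, 0.70, p)
        assert np.allclose(dy, 0.0, atol=1e-9)

    def test_rejects_bad_multiplier_and_nan_state(self, base_params):
        y = initial_state(base_params)
        with pytest.raises(ValueError):
            derivatives(y, 0.0, base_params, r_tv_multiplier=0.5)
        y[3] = float("nan")
        with pytest.raises(SimulationError):
            derivatives(y, 0.0, base_params)


def _isolated_rc_params():
    """All paths blocked except the splanchnic bed's outflow into a vast
    venous reservoir: a pure RC discharge."""
    p = default_parameters()
    blocked = 1e9
    beds = [replace(b, r_out=blocked) for b in p.beds]
    beds[0] = replace(beds[0], compliance=0.1, r_out=5.0)  # tau = 0.5 s
    return replace(
        p,
        aorta=replace(p.aorta, r_out=blocked),
        beds=tuple(beds),
        systemic_veins=replace(p.systemic_veins, compliance=1e9, r_out=blocked),
        thoracic_veins=replace(p.thoracic_veins, r_out=blocked),
        pulmonary_arteries=replace(p.pulmonary_arteries, r_out=blocked),
        pulmonary_veins=replace(p.pulmonary_veins, r_out=blocked),
        r_mitral=blocked, r_aortic=blocked, r_tricuspid=blocked,
        r_pulmonic=blocked,
    )


class TestIntegration:
    def test_isolated_rc_discharge_matches_closed_form(self):
        p = _isolated_rc_params()
        p0 = 50.0
        y0 = initial_state(p)
        y0[5] = p.beds[0].v_unstressed + p0 * p.beds[0].compliance
        trace = simulate(p, 1.0, y0=y0)
        pressure = (trace.volumes[:, 5] - p.beds[0].v_unstressed) / p.beds[0].compliance
        tau = p.beds[0].compliance * p.beds[0].r_out
        exact = p0 * np.exp(-trace.time / tau)
        assert np.max(np.abs(pressure - exact)) / p0 < 1e-3

    def test_sample_and_pacing_counts(self, short_trace):
        assert short_trace.time.size == 10_001
        assert short_trace.pacing_times.size == 14
        spacing = np.diff(short_trace.pacing_times)
        assert np.allclose(spacing, 60.0 / 80.0, rtol=0, atol=1e-12)

    def test_blood_volume_conserved(self, short_trace):
        total = short_trace.total_volume
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-3

    def test_halving_dt_leaves_stroke_volume(self, base_params):
        from vvcsim.pv_analysis import beat_metrics, segment_beats
        sv = []
        for dt in (2.5e-4, 1.25e-4):
            tr = simulate(base_params, 30.0, dt=dt)
            sv.append(beat_metrics(segment_beats(tr)[-1]).sv)
        assert abs(sv[1] - sv[0]) / sv[0] < 2e-3

    def test_rejects_bad_sampling_and_duration(self, base_params):
        with pytest.raises(ValueError):
            simulate(base_params, -1.0)
        with pytest.raises(ValueError):
            simulate(base_params, 1.0, sample_interval=3.3e-4)

    def test_instability_raises_with_diagnostic(self, base_params):
        with pytest.raises(SimulationError):
            simulate(base_params, 2.0, sample_interval=0.4, dt=0.1)

    def test_valves_never_carry_negative_flow(self, short_trace):
        assert np.min(short_trace.aortic_inflow) >= 0.0
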