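import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vvcsim.pv_analysis import (
    arterial_metrics,
    beat_metrics,
    fit_espvr,
    mechanical_efficiency,
    preload_sensitivity,
    pva,
    relation_stats,
    segment_beats,
)
from vvcsim.pv_analysis import Beat, BeatMetrics, ESPVRFit
from vvcsim.synthetic import FixtureLoopSpec, make_rect_loop, make_trace_from_loops

# reported normal-level steady-state values, used as exact fixture inputs
NORMAL_LOOP = FixtureLoopSpec(edv=100.5, esv=54.1, plateau_pressure=81.7,
                              baseline_pressure=5.0)


def _metrics(spec=NORMAL_LOOP):
    return beat_metrics(make_rect_loop(spec))


def _trapezoid_loop_integral(v, p):
    """Independent oracle: trapezoidal closed-contour integral of P dV."""
    v2 = np.append(v, v[0])
    p2 = np.append(p, p[0])
    return abs(float(np.sum(0.5 * (p2[1:] + p2[:-1]) * np.diff(v2))))


class TestSegmentation:
    def test_simulated_trace_yields_thirteen_beats(self, short_trace):
        beats = segment_beats(short_trace)
        assert len(beats) == 13
        for b, t0 in zip(beats, short_trace.pacing_times):
            assert b.onset_time == t0
            assert b.time[-1] - b.time[0] == pytest.approx(0.75, abs=1e-9)

    def test_beats_partition_the_trace(self, short_trace):
        beats = segment_beats(short_trace)
        interior = np.concatenate([b.time[:-1] for b in beats])
        covered = short_trace.time[(short_trace.time < beats[-1].time[-1])]
        assert np.array_equal(interior, covered)

    def test_synthetic_round_trip_is_exact(self):
        loops = [make_rect_loop(NORMAL_LOOP) for _ in range(5)]
        trace = make_trace_from_loops(loops)
        recovered = segment_beats(trace)
        assert len(recovered) == 5
        truth = beat_metrics(loops[0])
        for b in recovered:
            m = beat_metrics(b)
            assert m.sv == truth.sv
            assert m.sw == truth.sw
            assert m.edv == truth.edv and m.esv == truth.esv

    def test_rejects_traces_without_two_pacings(self, short_trace):
        import dataclasses
        bad = dataclasses.replace(short_trace, pacing_times=np.array([0.0]))
        with pytest.raises(ValueError):
            segment_beats(bad)


class TestBeatMetrics:
    def test_rectangular_loop_scalars(self):
        m = _metrics()
        assert m.sv == pytest.approx(46.4, abs=1e-12)
        assert m.sw == pytest.approx(46.4 * 76.7, abs=1e-9)
        assert m.edv == 100.5 and m.esv == 54.1
        assert m.pes == pytest.approx(81.7) and m.edp == pytest.approx(5.0)
        assert m.pp == pytest.approx(76.7)

    def test_shoelace_equals_trapezoid_integral(self):
        for spec in (NORMAL_LOOP,
                     FixtureLoopSpec(140.1, 87.4, 133.6, 8.4, samples_per_segment=7)):
            b = make_rect_loop(spec)
            m = beat_metrics(b)
            oracle = _trapezoid_loop_integral(b.lv_volume, b.lv_pressure)
            assert abs(m.sw - oracle) <= 1e-9 * oracle

    def test_stroke_work_invariant_to_loop_starting_point(self):
        b = make_rect_loop(NORMAL_LOOP)
        sw0 = beat_metrics(b).sw
        for shift in (3, 17, 50):
            rolled = Beat(
                time=b.time[:-1],
                lv_pressure=np.roll(b.lv_pressure[:-1], shift),
                lv_volume=np.roll(b.lv_volume[:-1], shift),
                aortic_pressure=np.roll(b.aortic_pressure[:-1], shift),
                onset_time=0.0,
            )
            assert beat_metrics(rolled).sw == pytest.approx(sw0, rel=1e-12)

    def test_constant_volume_beat_flagged_non_ejecting(self):
        t = np.linspace(0, 0.75, 50)
        b = Beat(time=t, lv_pressure=np.full(50, 20.0),
                 lv_volume=np.full(50, 80.0), aortic_pressure=np.full(50, 90.0),
                 onset_time=0.0)
        m = beat_metrics(b)
        assert m.sv == 0.0 and m.sw == 0.0 and not m.ejecting


class TestESPVR:
    def test_collinear_points_recovered_exactly(self):
        esv = np.array([40.0, 55.0, 63.0, 70.0, 85.0])
        fit = fit_espvr(list(zip(esv, 1.8 * (esv - 20.0))))
        assert fit.ees == pytest.approx(1.8, rel=1e-12)
        assert fit.v0 == pytest.approx(20.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_point_order_irrelevant(self):
        pts = [(40.0, 30.0), (50.0, 52.0), (60.0, 71.0), (70.0, 93.0)]
        f1 = fit_espvr(pts)
        f2 = fit_espvr(pts[::-1])
        assert (f1.ees, f1.v0, f1.r_squared) == (f2.ees, f2.v0, f2.r_squared)

    def test_symmetric_noise_keeps_slope(self):
        esv = np.arange(40.0, 82.0, 4.0)
        pes = 1.8 * (esv - 20.0)
        eps = 0.5
        pes[2] += eps
        pes[7] -= eps  # symmetric about the x-mean: slope shifts < eps bound
        fit = fit_espvr(list(zip(esv, pes)))
        assert abs(fit.ees - 1.8) < eps

    @given(st.floats(0.5, 4.0), st.floats(-10.0, 40.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_recovery_for_any_line(self, ees, v0):
        esv = np.linspace(v0 + 20, v0 + 70, 8)
        fit = fit_espvr(list(zip(esv, ees * (esv - v0))))
        assert fit.ees == pytest.approx(ees, rel=1e-9)
        assert fit.v0 == pytest.approx(v0, rel=1e-6, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_espvr([(50.0, 60.0), (50.0, 70.0), (50.0, 80.0)])
        with pytest.raises(ValueError):
            fit_espvr([(50.0, 60.0), (60.0, 70.0)])


class TestEnergetics:
    FIT = ESPVRFit(ees=1.8, v0=20.0, r_squared=1.0, n_beats=12)

    def _m(self, **kw):
        base = dict(edv=100.5, esv=54.1, sv=46.4, pes=81.7, edp=5.0, pp=76.7,
                    dpdt_max=1000.0, sw=3558.88, onset_time=0.0, ejecting=True)
        base.update(kw)
        return BeatMetrics(**base)

    def test_pva_is_sw_plus_triangle(self):
        assert pva(self._m(), self.FIT) == pytest.approx(
            3558.88 + 0.5 * 81.7 * 34.1, abs=1e-9)

    def test_pva_reduces_to_sw_at_intercept(self):
        assert pva(self._m(esv=20.0), self.FIT) == pytest.approx(3558.88)
        # below the intercept the potential-energy term clamps at zero
        assert pva(self._m(esv=15.0), self.FIT) == pytest.approx(3558.88)

    def test_pva_never_below_sw(self):
        for esv in (10.0, 25.0, 54.1, 90.0):
            assert pva(self._m(esv=esv), self.FIT) >= 3558.88

    def test_efficiency_values(self):
        assert mechanical_efficiency(100.0, 100.0) == 100.0
        assert round(mechanical_efficiency(3558.88, 4951.865), 2) == 71.87

    def test_efficiency_falls_as_potential_energy_grows(self):
        sw = 3000.0
        vals = [mechanical_efficiency(sw, sw + pe) for pe in (0, 500, 1500, 4000)]
        assert vals == sorted(vals, reverse=True)

    def test_efficiency_rejects_nonpositive_pva(self):
        with pytest.raises(ValueError):
            mechanical_efficiency(10.0, 0.0)


class TestArterialMetrics:
    @pytest.mark.parametrize(
        "sv,pes,pp,art_ea,art_ca,eadyn",
        [
            (46.5, 81.7, 33.4, 1.76, 0.57, 0.72),   # normal level, as reported
            (52.7, 133.6, 106.6, 2.54, 0.39, 2.02),  # stiff level, as reported
        ],
    )
    def test_reported_two_decimal_indices(self, sv, pes, pp, art_ea, art_ca, eadyn):
        m = BeatMetrics(edv=0, esv=0, sv=sv, pes=pes, edp=0, pp=pp,
                        dpdt_max=0, sw=0, onset_time=0, ejecting=True)
        a = arterial_metrics(m)
        assert round(a.art_ea, 2) == art_ea
        assert round(a.art_ca, 2) == art_ca
        assert round(a.eadyn, 2) == eadyn

    @given(st.floats(5.0, 120.0), st.floats(20.0, 250.0), st.floats(5.0, 150.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_reciprocal_identity(self, sv, pes, pp):
        m = BeatMetrics(edv=0, esv=0, sv=sv, pes=pes, edp=0, pp=pp,
                        dpdt_max=0, sw=0, onset_time=0, ejecting=True)
        a = arterial_metrics(m)
        assert a.art_ca * a.art_ea == pytest.approx(1.0, abs=1e-12)
        assert a.eadyn / a.art_ea == pytest.approx(pp / pes, rel=1e-12)

    def test_non_ejecting_beat_flagged_undefined(self):
        m = BeatMetrics(edv=80, esv=80, sv=0.0, pes=50, edp=5, pp=10,
                        dpdt_max=0, sw=0, onset_time=0, ejecting=False)
        a = arterial_metrics(m)
        assert not a.defined and np.isnan(a.art_ca)


class TestRelationStats:
    def test_exactly_linear(self):
        x = np.arange(1.0, 11.0)
        rs = relation_stats(x, 3.0 * x + 2.0)
        assert rs.r_squared_linear == pytest.approx(1.0, abs=1e-12)
        assert rs.curvature_index == pytest.approx(0.0, abs=1e-6)
        assert rs.slope == pytest.approx(3.0) and rs.intercept == pytest.approx(2.0)

    def test_quadratic_data_is_strongly_curved(self):
        x = np.arange(1.0, 11.0)
        rs = relation_stats(x, x**2)
        assert rs.curvature_index > 0.9

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 20)
        y = 2 * x + 0.3 * x**2 + rng.normal(0, 0.5, 20)
        perm = rng.permutation(20)
        r1 = relation_stats(x, y)
        r2 = relation_stats(x[perm], y[perm])
        assert r1.slope == pytest.approx(r2.slope, rel=1e-9)
        assert r1.curvature_index == pytest.approx(r2.curvature_index, rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            relation_stats([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            relation_stats([1, 2, 3], [1, 2, 3])


class TestPreloadSensitivity:
    def test_constant_series_has_zero_cv(self):
        assert preload_sensitivity([2.0, 2.0, 2.0, 2.0]) == 0.0

    def test_direct_formula_oracle(self):
        x = np.array([1.0, 1.0, 1.0, 3.0])
        expected = float(np.sqrt(np.mean((x - x.mean()) ** 2)) / x.mean())
        assert preload_sensitivity(x) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        x = np.array([1.0, 2.0, 4.0, 5.5, 3.0])
        assert preload_sensitivity(k * x) == pytest.approx(
            preload_sensitivity(x), rel=1e-9)

    def test_rejects_nonpositive_mean_and_short_series(self):
        with pytest.raises(ValueError):
            preload_sensitivity([-1.0, -2.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            preload_sensitivity([1.0, 2.0, 3.0])
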