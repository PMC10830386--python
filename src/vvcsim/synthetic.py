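"""Analytic synthetic fixtures with exact ground truth.

The analytics pipeline must be testable independently of the ODE model, so
this module builds polygonal PV loops (whose stroke work is exact polygon
area), collinear or noisy end-systolic point sets, and assembled traces
whose segmentation round-trips to the generating loops bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import SimulationTrace
from .pv_analysis import Beat

__all__ = [
    "FixtureLoopSpec",
    "make_rect_loop",
    "make_espvr_points",
    "make_trace_from_loops",
]


@dataclass(frozen=True)
class FixtureLoopSpec:
    """A rectangular PV loop: filling at baseline pressure, ejection at a
    plateau, with exact stroke work (EDV-ESV)*(plateau-baseline)."""

    edv: float
    esv: float
    plateau_pressure: float
    baseline_pressure: float
    samples_per_segment: int = 25

    def __post_init__(self) -> None:
        if not self.edv > self.esv:
            raise ValueError("require edv > esv")
        if not self.plateau_pressure > self.baseline_pressure:
            raise ValueError("require plateau_pressure > baseline_pressure")
        if self.samples_per_segment < 2:
            raise ValueError("samples_per_segment must be >= 2")

    @property
    def true_sv(self) -> float:
        return self.edv - self.esv

    @property
    def true_sw(self) -> float:
        return (self.edv - self.esv) * (self.plateau_pressure - self.baseline_pressure)


def make_rect_loop(spec: FixtureLoopSpec, period: float = 0.75) -> Beat:
    """Build one rectangular counter-clockwise PV loop as a Beat.

    Four linear segments: filling (ESV->EDV at baseline pressure),
    isovolumic contraction (EDV, baseline->plateau), ejection (EDV->ESV at
    plateau), isovolumic relaxation (ESV, plateau->baseline).  The fixture's
    aortic pressure mirrors the LV pressure, so the beat's pulse pressure is
    plateau minus baseline.
    """
    n = spec.samples_per_segment

    def seg(a, b):
        return np.linspace(a, b, n, endpoint=False)

    v = np.concatenate([
        seg(spec.esv, spec.edv),
        np.full(n, spec.edv),
        seg(spec.edv, spec.esv),
        np.full(n, spec.esv),
    ])
    p = np.concatenate([
        np.full(n, spec.baseline_pressure),
        seg(spec.baseline_pressure, spec.plateau_pressure),
        np.full(n, spec.plateau_pressure),
        seg(spec.plateau_pressure, spec.baseline_pressure),
    ])
    # close the loop with the starting vertex so min/max and area are exact
    v = np.append(v, spec.esv)
    p = np.append(p, spec.baseline_pressure)
    t = np.linspace(0.0, period, v.size)
    return Beat(time=t, lv_pressure=p, lv_volume=v, aortic_pressure=p.copy(),
                onset_time=0.0)


def make_espvr_points(
    ees: float,
    v0: float,
    esv_values,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """(ESV, Pes) pairs on the line Pes = Ees*(ESV - V0), plus seeded noise."""
    if ees <= 0:
        raise ValueError("ees must be > 0")
    esv = np.asarray(esv_values, dtype=float)
    pes = ees * (esv - v0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pes = pes + rng.normal(0.0, noise_sd, size=esv.shape)
    return list(zip(esv.tolist(), pes.tolist()))


def make_trace_from_loops(loops, period: float = 0.75) -> SimulationTrace:
    """Concatenate beats into a trace segmentable back into the same loops.

    Each input loop is resampled onto a uniform grid spanning one period
    (its own sample positions are preserved when already uniform, as those
    from :func:`make_rect_loop` are); consecutive loops share the boundary
    sample, and pacing times sit at the loop boundaries.
    """
    loops = list(loops)
    if not loops:
        raise ValueError("need at least one loop")
    n = loops[0].time.size
    dt = period / (n - 1)
    times = [np.array([0.0])]
    lv_p = [loops[0].lv_pressure[:1]]
    lv_v = [loops[0].lv_volume[:1]]
    ao_p = [loops[0].aortic_pressure[:1]]
    for k, loop in enumerate(loops):
        if loop.time.size != n:
            raise ValueError("all loops must share one sample count")
        t0 = k * period
        times.append(t0 + loop.time[1:])
        lv_p.append(loop.lv_pressure[1:])
        lv_v.append(loop.lv_volume[1:])
        ao_p.append(loop.aortic_pressure[1:])
    time = np.concatenate(times)
    # first sample of the trace is the first loop's first sample
    lv_pressure = np.concatenate(lv_p)
    lv_volume = np.concatenate(lv_v)
    aortic_pressure = np.concatenate(ao_p)
    pacing = np.arange(len(loops) + 1) * period
    return SimulationTrace(
        time=time,
        lv_pressure=lv_pressure,
        lv_volume=lv_volume,
        aortic_pressure=aortic_pressure,
        aortic_inflow=np.zeros_like(time),
        thoracic_vein_flow=np.zeros_like(time),
        pacing_times=pacing,
        sample_interval=dt,
        volumes=lv_volume[:, None].copy(),
        heart_period=period,
    )
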