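"""Closed-loop cardiovascular ODE system and fixed-step integrator.

The state vector holds one volume per compartment (mL):

====  =======================
index compartment
====  =======================
0     left atrium
1     left ventricle
2     right atrium
3     right ventricle
4     proximal aorta
5-9   peripheral beds (splanchnic, extra-splanchnic, skeletal muscle,
      brain, coronary)
10    systemic veins
11    thoracic veins (vena-caval occlusion site on its outflow)
12    pulmonary arteries
13    pulmonary veins
====  =======================

A 15th state variable carries the aortic-root flow: ejection through the
aortic valve is governed by an inertance, so flow persists past peak
elastance (the physiologic mechanism that gives a ~0.3 s ejection phase and
a realistic pulse pressure).  The mitral, tricuspid and pulmonic valves are
ideal resistive diodes (flow only down the pressure gradient, no
regurgitation), and the aortic valve is a diode too: its flow state is
clamped at zero whenever momentum would reverse it.  Every flow enters one
compartment's volume derivative positively and another's negatively, so the
sum of the 14 volume derivatives is zero by construction and total blood
volume is conserved exactly up to round-off.

Integration is fixed-step classical 4th-order Runge-Kutta (default step
0.25 ms) with output resampled on a uniform grid (default 1 ms).  The loop
is compiled with numba; results are deterministic across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .parameters import ChamberParams, ModelParameters

__all__ = [
    "SimulationTrace",
    "SimulationError",
    "COMPARTMENT_NAMES",
    "elastance_at",
    "chamber_pressure",
    "valve_flow",
    "derivatives",
    "initial_state",
    "simulate",
    "pack_parameters",
]

COMPARTMENT_NAMES = (
    "la", "lv", "ra", "rv", "aorta",
    "bed_splanchnic", "bed_extrasplanchnic", "bed_skeletal_muscle",
    "bed_brain", "bed_coronary",
    "systemic_veins", "thoracic_veins",
    "pulmonary_arteries", "pulmonary_veins",
)
_NVOL = 14  # volume states; state 14 is the aortic-root flow (mL/s)
_N = 15

# Packed-parameter vector layout (see pack_parameters):
#   [0]                period (s)
#   [1 + 6k : 7 + 6k]  chamber k in (LA, LV, RA, RV):
#                      e_max, e_min, v0, t_act (s), delay (s), t_rise (s)
#   [25 + 3j : 28+3j]  compartment j in state order 4..13:
#                      compliance, r_out, v_unstressed
#   [55:59]            valve resistances: mitral, aortic, tricuspid, pulmonic
#   [59]               aortic-root inertance (mmHg*s^2/mL)
_NPARAM = 60


class SimulationError(RuntimeError):
    """Raised when integration produces a non-finite or non-conserving state."""


def pack_parameters(params: ModelParameters) -> np.ndarray:
    """Flatten a :class:`ModelParameters` into the kernel's float64 vector."""
    p = np.empty(_NPARAM)
    period = params.period
    p[0] = period
    for k, ch in enumerate((params.la, params.lv, params.ra, params.rv)):
        base = 1 + 6 * k
        t_act = ch.activation_duration_fraction * period
        p[base] = ch.e_max
        p[base + 1] = ch.e_min
        p[base + 2] = ch.v0
        p[base + 3] = t_act
        p[base + 4] = ch.activation_delay
        p[base + 5] = ch.activation_rise_fraction * t_act
    for j, comp in enumerate(params.compartments):
        base = 25 + 3 * j
        p[base] = comp.compliance
        p[base + 1] = comp.r_out
        p[base + 2] = comp.v_unstressed
    p[55] = params.r_mitral
    p[56] = params.r_aortic
    p[57] = params.r_tricuspid
    p[58] = params.r_pulmonic
    p[59] = params.aortic_inertance
    return p


# ---------------------------------------------------------------------------
# Scalar primitives (shared between the kernel and the public API)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _activation(t_in_cycle: float, delay: float, t_act: float, t_rise: float) -> float:
    """Squared-sine activation: sin^2 rise over t_rise, cos^2 fall over the
    rest of the window; 0 outside [delay, delay + t_act].  With
    t_rise = t_act/2 this is the symmetric squared half-sine."""
    tau = t_in_cycle - delay
    if tau < 0.0 or tau > t_act:
        return 0.0
    if tau <= t_rise:
        s = np.sin(0.5 * np.pi * tau / t_rise)
    else:
        s = np.cos(0.5 * np.pi * (tau - t_rise) / (t_act - t_rise))
    return s * s


@njit(cache=True)
def _valve_flow(p_up: float, p_down: float, r: float) -> float:
    if p_up > p_down:
        return (p_up - p_down) / r
    return 0.0


def elastance_at(t_in_cycle: float, chamber: ChamberParams, period: float) -> float:
    """Instantaneous chamber elastance (mmHg/mL) at a time within the cycle."""
    if not (np.isfinite(t_in_cycle) and np.isfinite(period)):
        raise ValueError("non-finite input")
    if not 0.0 <= t_in_cycle < period:
        raise ValueError("t_in_cycle must lie in [0, period)")
    t_act = chamber.activation_duration_fraction * period
    a = _activation(t_in_cycle, chamber.activation_delay, t_act,
                    chamber.activation_rise_fraction * t_act)
    return chamber.e_min + (chamber.e_max - chamber.e_min) * a


def chamber_pressure(volume: float, elastance: float, v0: float) -> float:
    """Linear elastance pressure ``E * (V - v0)``; may be transiently negative."""
    if not np.isfinite(volume):
        raise ValueError("volume must be finite")
    return elastance * (volume - v0)


def valve_flow(p_upstream: float, p_downstream: float, r_valve: float) -> float:
    """Ideal-diode valve flow (mL/s); never negative."""
    if r_valve <= 0:
        raise ValueError("r_valve must be > 0")
    return _valve_flow(p_upstream, p_downstream, r_valve)


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

@njit(cache=True)
def _derivatives(y, t, p, r_tv_mult, dydt):
    period = p[0]
    tc = t % period

    # chamber pressures
    p_ch = np.empty(4)
    for k in range(4):
        base = 1 + 6 * k
        a = _activation(tc, p[base + 4], p[base + 3], p[base + 5])
        e = p[base + 1] + (p[base] - p[base + 1]) * a
        p_ch[k] = e * (y[k] - p[base + 2])
    p_la, p_lv, p_ra, p_rv = p_ch[0], p_ch[1], p_ch[2], p_ch[3]

    # passive compartment pressures (state indices 4..13)
    p_c = np.empty(10)
    for j in range(10):
        base = 25 + 3 * j
        p_c[j] = (y[4 + j] - p[base + 2]) / p[base]
    p_ao = p_c[0]
    p_sv = p_c[6]
    p_tv = p_c[7]
    p_pa = p_c[8]
    p_pv = p_c[9]

    r_ao_branch = p[26]       # aorta r_out, per bed branch
    r_sv = p[25 + 3 * 6 + 1]  # systemic veins r_out
    r_tv = p[25 + 3 * 7 + 1]  # thoracic veins r_out (occlusion site)
    r_pa = p[25 + 3 * 8 + 1]
    r_pv = p[25 + 3 * 9 + 1]

    q_mitral = _valve_flow(p_la, p_lv, p[55])
    q_tricuspid = _valve_flow(p_ra, p_rv, p[57])
    q_pulmonic = _valve_flow(p_rv, p_pa, p[58])

    # aortic valve: inertial diode.  y[14] is the root flow; it only feeds
    # the volume balance while positive, and its momentum equation is
    # frozen once the valve is shut (flow <= 0 with an adverse gradient).
    q_av_state = y[14]
    q_aortic = q_av_state if q_av_state > 0.0 else 0.0
    if q_av_state > 0.0 or p_lv > p_ao:
        dydt[14] = (p_lv - p_ao - p[56] * q_aortic) / p[59]
    else:
        dydt[14] = 0.0

    q_pv_la = (p_pv - p_la) / r_pv
    q_sv_tv = (p_sv - p_tv) / r_sv
    q_tv_ra = (p_tv - p_ra) / (r_tv * r_tv_mult)
    q_pa_pv = (p_pa - p_pv) / r_pa

    dydt[0] = q_pv_la - q_mitral           # LA
    dydt[1] = q_mitral - q_aortic          # LV
    dydt[2] = q_tv_ra - q_tricuspid        # RA
    dydt[3] = q_tricuspid - q_pulmonic     # RV

    q_ao_out = 0.0
    q_beds_out = 0.0
    for i in range(5):
        p_bed = p_c[1 + i]
        r_bed = p[25 + 3 * (1 + i) + 1]
        q_in = (p_ao - p_bed) / r_ao_branch
        q_out = (p_bed - p_sv) / r_bed
        dydt[5 + i] = q_in - q_out
        q_ao_out += q_in
        q_beds_out += q_out

    dydt[4] = q_aortic - q_ao_out          # aorta
    dydt[10] = q_beds_out - q_sv_tv        # systemic veins
    dydt[11] = q_sv_tv - q_tv_ra           # thoracic veins
    dydt[12] = q_pulmonic - q_pa_pv        # pulmonary arteries
    dydt[13] = q_pa_pv - q_pv_la           # pulmonary veins


@njit(cache=True)
def _vco_multiplier(t, start, ramp, max_mult):
    if t < start:
        return 1.0
    if t < start + ramp:
        return 1.0 + (max_mult - 1.0) * (t - start) / ramp
    return max_mult


@njit(cache=True)
def _integrate(y0, duration, dt, stride, p, vco_start, vco_ramp, vco_max):
    n_steps = int(round(duration / dt))
    n_samples = n_steps // stride + 1
    times = np.empty(n_samples)
    states = np.empty((n_samples, y0.shape[0]))
    y = y0.copy()
    times[0] = 0.0
    states[0] = y
    k1 = np.empty_like(y)
    k2 = np.empty_like(y)
    k3 = np.empty_like(y)
    k4 = np.empty_like(y)
    yt = np.empty_like(y)
    i_sample = 1
    for i in range(n_steps):
        t = i * dt
        th = t + 0.5 * dt
        t1 = t + dt
        m0 = _vco_multiplier(t, vco_start, vco_ramp, vco_max)
        mh = _vco_multiplier(th, vco_start, vco_ramp, vco_max)
        m1 = _vco_multiplier(t1, vco_start, vco_ramp, vco_max)
        _derivatives(y, t, p, m0, k1)
        for j in range(y.shape[0]):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        _derivatives(yt, th, p, mh, k2)
        for j in range(y.shape[0]):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        _derivatives(yt, th, p, mh, k3)
        for j in range(y.shape[0]):
            yt[j] = y[j] + dt * k3[j]
        _derivatives(yt, t1, p, m1, k4)
        for j in range(y.shape[0]):
            y[j] = y[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if y[14] < 0.0:
            y[14] = 0.0  # aortic valve shuts: no regurgitant momentum
        if (i + 1) % stride == 0:
            times[i_sample] = t1
            states[i_sample] = y
            i_sample += 1
    return times[:i_sample], states[:i_sample]


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def derivatives(
    state: np.ndarray,
    t: float,
    params: ModelParameters,
    r_tv_multiplier: float = 1.0,
) -> np.ndarray:
    """Volume derivatives (mL/s) of every compartment; sums to zero."""
    state = np.asarray(state, dtype=float)
    if state.shape != (_N,):
        raise ValueError(f"state must have shape ({_N},): 14 volumes + aortic root flow")
    if not np.all(np.isfinite(state)):
        raise SimulationError("non-finite state")
    if r_tv_multiplier < 1.0:
        raise ValueError("r_tv_multiplier must be >= 1")
    p = pack_parameters(params)
    out = np.empty(_N)
    _derivatives(state, float(t), p, float(r_tv_multiplier), out)
    return out


def initial_state(params: ModelParameters) -> np.ndarray:
    """A physiologically plausible initial volume distribution.

    Compartments are seeded at round-number resting pressures; whatever
    volume remains (total blood volume minus the seeded volumes) is placed in
    the systemic veins.  Transients wash out over the pre-occlusion settling
    window, so the split only needs to keep every volume positive.
    """
    seed_pressures = {
        "aorta": 90.0, "bed": 85.0, "thoracic_veins": 4.5,
        "pulmonary_arteries": 15.0, "pulmonary_veins": 8.0,
    }
    y = np.empty(_N)
    y[0] = params.la.v0 + 45.0    # LA
    y[1] = params.lv.v0 + 90.0    # LV
    y[2] = params.ra.v0 + 45.0    # RA
    y[3] = params.rv.v0 + 95.0    # RV
    y[4] = params.aorta.v_unstressed + seed_pressures["aorta"] * params.aorta.compliance
    for i, bed in enumerate(params.beds):
        y[5 + i] = bed.v_unstressed + seed_pressures["bed"] * bed.compliance
    tv = params.thoracic_veins
    y[11] = tv.v_unstressed + seed_pressures["thoracic_veins"] * tv.compliance
    pa = params.pulmonary_arteries
    y[12] = pa.v_unstressed + seed_pressures["pulmonary_arteries"] * pa.compliance
    pv = params.pulmonary_veins
    y[13] = pv.v_unstressed + seed_pressures["pulmonary_veins"] * pv.compliance
    y[14] = 0.0  # aortic root flow starts at rest
    y[10] = 0.0
    y[10] = params.total_blood_volume - y[:_NVOL].sum()
    if y[10] <= 0:
        raise ValueError("total_blood_volume too small for the seeded distribution")
    return y


@dataclass
class SimulationTrace:
    """Uniformly sampled simulation output.

    ``volumes`` holds the full state history (one column per compartment in
    :data:`COMPARTMENT_NAMES` order); the named series are derived views used
    by the pressure-volume analytics.
    """

    time: np.ndarray
    lv_pressure: np.ndarray
    lv_volume: np.ndarray
    aortic_pressure: np.ndarray
    aortic_inflow: np.ndarray
    thoracic_vein_flow: np.ndarray
    pacing_times: np.ndarray
    sample_interval: float
    volumes: np.ndarray = field(repr=False)
    heart_period: float = 0.0

    @property
    def total_volume(self) -> np.ndarray:
        return self.volumes[:, :_NVOL].sum(axis=1)


def _elastance_series(t: np.ndarray, period: float, ch: ChamberParams) -> np.ndarray:
    tc = np.mod(t, period)
    t_act = ch.activation_duration_fraction * period
    t_rise = ch.activation_rise_fraction * t_act
    tau = tc - ch.activation_delay
    rising = np.sin(0.5 * np.pi * np.clip(tau, 0, t_rise) / t_rise) ** 2
    falling = np.cos(0.5 * np.pi * (np.clip(tau, t_rise, t_act) - t_rise)
                     / (t_act - t_rise)) ** 2
    a = np.where(tau <= t_rise, rising, falling)
    a = np.where((tau >= 0) & (tau <= t_act), a, 0.0)
    return ch.e_min + (ch.e_max - ch.e_min) * a


def simulate(
    params: ModelParameters,
    duration: float,
    vco=None,
    sample_interval: float = 1e-3,
    dt: float = 2.5e-4,
    y0: np.ndarray | None = None,
) -> SimulationTrace:
    """Integrate the closed loop for ``duration`` seconds.

    ``vco`` is an optional :class:`~vvcsim.protocols.VCOSpec`; when given,
    the thoracic-vein outflow resistance is multiplied by its time-based
    ramp schedule.  Raises :class:`SimulationError` on instability or a
    blood-volume drift above 0.1%.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    stride = int(round(sample_interval / dt))
    if stride < 1 or abs(stride * dt - sample_interval) > 1e-12:
        raise ValueError("sample_interval must be a multiple of dt")
    p = pack_parameters(params)
    if y0 is None:
        y0 = initial_state(params)
    y0 = np.asarray(y0, dtype=float)

    if vco is None:
        vco_start, vco_ramp, vco_max = np.inf, 1.0, 1.0
    else:
        vco_start, vco_ramp, vco_max = vco.start_time, vco.ramp_duration, vco.max_multiplier

    times, states = _integrate(y0, float(duration), dt, stride, p,
                               vco_start, vco_ramp, vco_max)
    if not np.all(np.isfinite(states)):
        bad = int(np.argmax(~np.isfinite(states).all(axis=1)))
        raise SimulationError(
            f"integration unstable: non-finite state at t={times[bad]:.4f} s"
        )
    total0 = y0[:_NVOL].sum()
    drift = np.max(np.abs(states[:, :_NVOL].sum(axis=1) - total0)) / total0
    if drift > 1e-3:
        raise SimulationError(f"blood volume drift {drift:.2e} exceeds 0.1%")

    period = params.period
    e_lv = _elastance_series(times, period, params.lv)
    lv_volume = states[:, 1]
    lv_pressure = e_lv * (lv_volume - params.lv.v0)
    aortic_pressure = (states[:, 4] - params.aorta.v_unstressed) / params.aorta.compliance
    aortic_inflow = np.maximum(states[:, 14], 0.0)
    p_tv = (states[:, 11] - params.thoracic_veins.v_unstressed) / params.thoracic_veins.compliance
    e_ra = _elastance_series(times, period, params.ra)
    p_ra = e_ra * (states[:, 2] - params.ra.v0)
    mult = np.array([_vco_multiplier(t, vco_start, vco_ramp, vco_max) for t in times])
    tv_flow = (p_tv - p_ra) / (params.thoracic_veins.r_out * mult)

    n_pace = int(np.floor(duration / period + 1e-9)) + 1
    pacing_times = np.arange(n_pace) * period

    return SimulationTrace(
        time=times,
        lv_pressure=lv_pressure,
        lv_volume=lv_volume,
        aortic_pressure=aortic_pressure,
        aortic_inflow=aortic_inflow,
        thoracic_vein_flow=tv_flow,
        pacing_times=pacing_times,
        sample_interval=sample_interval,
        volumes=states,
        heart_period=period,
    )
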