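"""Experimental protocols: graded aortic stiffening and vena-caval occlusion.

The stiffening protocol replays five total-arterial-compliance / total-
systemic-resistance levels, from a normal human-scale aorta
(C_A = 0.7 mL/mmHg, R_T = 1.28 mmHg*s/mL) through 10%, 20% and 40%
compliance reductions to a rigid-conduit ("stiff") level
(C_A = 0.19 mL/mmHg, R_T = 3.66 mmHg*s/mL).  Each level is imposed by
proportionally scaling the aortic and peripheral-bed compliances and the
arterial resistances of the base parameter set.

The vena-caval occlusion (VCO) is a time-based ramp of the thoracic-vein
outflow resistance, applied after a long settling window so every level is
in periodic steady state when preload starts to fall.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import pv_analysis as pva
from .model_core import SimulationTrace, simulate
from .parameters import CompartmentParams, ModelParameters

__all__ = [
    "ComplianceLevel",
    "VCOSpec",
    "ExperimentResult",
    "LEVEL_NAMES",
    "standard_levels",
    "apply_level",
    "vco_multiplier",
    "default_vco",
    "run_experiment",
    "run_all_levels",
]

LEVEL_NAMES = ("Normal", "90%", "80%", "60%", "Stiff")


@dataclass(frozen=True)
class ComplianceLevel:
    """One arterial stiffening level: target C_A and R_T for the circuit."""

    name: str
    c_a_target: float  # mL/mmHg
    r_t_target: float  # mmHg*s/mL

    def __post_init__(self) -> None:
        if self.c_a_target <= 0 or self.r_t_target <= 0:
            raise ValueError("targets must be positive")


@dataclass(frozen=True)
class VCOSpec:
    """Schedule of the simulated vena-caval occlusion.

    The thoracic-vein outflow resistance is multiplied by a factor ramping
    linearly from 1 to ``max_multiplier`` over ``ramp_duration`` seconds
    starting at ``start_time``, then held at ``max_multiplier``.
    ``hold_duration`` sets how long past the ramp the experiment runs.
    """

    start_time: float = 180.0
    ramp_duration: float = 10.0
    hold_duration: float = 5.0
    max_multiplier: float = 41.0

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be > 0")
        if self.hold_duration < 0:
            raise ValueError("hold_duration must be >= 0")
        if self.max_multiplier < 1:
            raise ValueError("max_multiplier must be >= 1")

    @property
    def end_time(self) -> float:
        return self.start_time + self.ramp_duration + self.hold_duration


def default_vco() -> VCOSpec:
    """The study's occlusion schedule: 3-min settle, 10-s ramp, 5-s hold."""
    return VCOSpec()


def standard_levels() -> tuple[ComplianceLevel, ...]:
    """The five compliance/resistance levels, normal through stiff."""
    return (
        ComplianceLevel("Normal", 0.70, 1.28),
        ComplianceLevel("90%", 0.63, 1.41),
        ComplianceLevel("80%", 0.56, 1.54),
        ComplianceLevel("60%", 0.42, 1.805),
        ComplianceLevel("Stiff", 0.19, 3.66),
    )


def apply_level(base: ModelParameters, level: ComplianceLevel) -> ModelParameters:
    """Scale the arterial side of ``base`` to hit a level's C_A and R_T.

    Compliances of the aorta and the five beds are scaled by a common factor
    so the derived total arterial compliance equals ``c_a_target``; arterial
    resistances (per-branch proximal aortic and bed outflow) are scaled by a
    common factor chosen so the derived total systemic resistance (which
    includes the untouched venous resistances) equals ``r_t_target``.
    Venous and valve parameters are left unchanged.
    """
    c_scale = level.c_a_target / base.total_arterial_compliance
    r_arterial_target = level.r_t_target - base.venous_resistance
    if r_arterial_target <= 0:
        raise ValueError("r_t_target does not exceed the fixed venous resistance")
    r_scale = r_arterial_target / base.arterial_resistance
    if c_scale <= 0 or r_scale <= 0:
        raise ValueError("scale factors must be positive")

    def scaled(comp: CompartmentParams) -> CompartmentParams:
        return replace(comp, compliance=comp.compliance * c_scale,
                       r_out=comp.r_out * r_scale)

    return replace(
        base,
        aorta=scaled(base.aorta),
        beds=tuple(scaled(b) for b in base.beds),
    )


def vco_multiplier(t: float, spec: VCOSpec) -> float:
    """Thoracic-vein resistance multiplier at time ``t`` (continuous, >= 1)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t < spec.start_time:
        return 1.0
    if t < spec.start_time + spec.ramp_duration:
        return 1.0 + (spec.max_multiplier - 1.0) * (t - spec.start_time) / spec.ramp_duration
    return spec.max_multiplier


@dataclass
class ExperimentResult:
    """One level's full occlusion experiment with per-beat analytics."""

    level: ComplianceLevel
    trace: SimulationTrace
    beats: list  # list[pva.BeatMetrics], one per complete beat
    arterial: list  # list[pva.ArterialMetrics], aligned with beats
    espvr: "pva.ESPVRFit"
    steady_state_beat_index: int  # last pre-occlusion beat
    vco_beat_indices: list  # beats whose pacing onset lies in the VCO window

    @property
    def steady_state(self) -> "pva.BeatMetrics":
        return self.beats[self.steady_state_beat_index]

    @property
    def steady_state_arterial(self) -> "pva.ArterialMetrics":
        return self.arterial[self.steady_state_beat_index]

    @property
    def vco_beats(self) -> list:
        return [self.beats[i] for i in self.vco_beat_indices]

    @property
    def vco_arterial(self) -> list:
        return [self.arterial[i] for i in self.vco_beat_indices]


def run_experiment(
    base: ModelParameters,
    level: ComplianceLevel,
    vco: VCOSpec | None = None,
) -> ExperimentResult:
    """Simulate one stiffening level through its occlusion and analyze it.

    The run covers the full settling window plus the occlusion ramp and
    hold.  Beats are segmented at pacing onsets; the last beat starting
    before the occlusion is the steady-state reference beat, and beats with
    onset inside ``[start_time, end_time)`` form the transient (VCO)
    analysis window.  The end-systolic pressure-volume relation is fitted
    over the VCO beats only, then used to attach pressure-volume area and
    mechanical efficiency to every beat.
    """
    if vco is None:
        vco = default_vco()
    params = apply_level(base, level)
    trace = simulate(params, vco.end_time, vco=vco)
    segments = pva.segment_beats(trace)
    beats = [pva.beat_metrics(b) for b in segments]

    onsets = np.array([b.onset_time for b in segments])
    pre = np.nonzero(onsets < vco.start_time - 1e-9)[0]
    if pre.size == 0:
        raise ValueError("no pre-occlusion beats; lengthen start_time")
    steady_idx = int(pre[-1])
    vco_idx = [int(i) for i in np.nonzero(
        (onsets >= vco.start_time - 1e-9) & (onsets < vco.end_time - 1e-9))[0]]
    if len(vco_idx) < 3:
        raise ValueError("occlusion window too short to analyze")

    fit = pva.fit_espvr([(beats[i].esv, beats[i].pes) for i in vco_idx])
    for m in beats:
        m.pva = pva.pva(m, fit)
        m.me = pva.mechanical_efficiency(m.sw, m.pva) if m.pva > 0 else float("nan")
    arterial = [pva.arterial_metrics(m) for m in beats]

    return ExperimentResult(
        level=level,
        trace=trace,
        beats=beats,
        arterial=arterial,
        espvr=fit,
        steady_state_beat_index=steady_idx,
        vco_beat_indices=vco_idx,
    )


def run_all_levels(
    base: ModelParameters,
    vco: VCOSpec | None = None,
) -> tuple[ExperimentResult, ...]:
    """Run the occlusion experiment at every standard stiffening level."""
    return tuple(run_experiment(base, level, vco) for level in standard_levels())
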