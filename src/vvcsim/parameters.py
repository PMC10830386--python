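"""Parameter containers for the closed-loop cardiovascular model.

The model is a classic lumped-parameter ("windkessel") circulation: four
time-varying-elastance chambers (LA, LV, RA, RV) connected through ideal
resistive diode valves to a systemic circuit (proximal aorta, five parallel
peripheral beds, systemic and thoracic veins) and a two-compartment pulmonary
circuit.  Units are fixed globally: pressures in mmHg, volumes in mL, times
in seconds, so compliances are mL/mmHg, resistances mmHg*s/mL and elastances
mmHg/mL.

Two derived quantities drive the stiffening protocol:

* ``total_arterial_compliance`` (C_A) -- the sum of the aortic and the five
  peripheral-bed compliances.
* ``total_systemic_resistance`` (R_T) -- the series resistance seen between
  the aortic root and the right atrium: the effective proximal aortic
  resistance, the parallel combination of the five peripheral-bed outflow
  resistances, and the (small) venous outflow resistances.

Each of the five aorta-to-bed branches carries the aorta's outflow resistance
``aorta.r_out``, so the effective proximal resistance is ``aorta.r_out / 5``.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, fields, replace
from pathlib import Path

__all__ = [
    "ChamberParams",
    "CompartmentParams",
    "ModelParameters",
    "BED_NAMES",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

#: Names of the five parallel systemic vascular beds, in state-vector order.
BED_NAMES = ("splanchnic", "extrasplanchnic", "skeletal_muscle", "brain", "coronary")


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ChamberParams:
    """A time-varying-elastance cardiac chamber.

    Chamber pressure is ``E(t) * (V - v0)`` where the elastance ``E(t)``
    varies between ``e_min`` (diastole) and ``e_max`` (peak systole) under a
    squared-sine activation starting ``activation_delay`` seconds after the
    pacing stimulus and lasting ``activation_duration_fraction`` of the
    pacing period.  The activation rises as sin^2 over the first
    ``activation_rise_fraction`` of the window and falls as cos^2 over the
    rest; 0.5 gives the symmetric squared half-sine.  Ventricles use a
    slower relaxation limb (rise fraction < 0.5), the physiologic shape that
    sustains ejection through late systole.
    """

    e_max: float
    e_min: float
    v0: float
    activation_duration_fraction: float
    activation_delay: float
    activation_rise_fraction: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_finite(f.name, getattr(self, f.name))
        if not self.e_max > self.e_min > 0:
            raise ValueError("require e_max > e_min > 0")
        if not 0 < self.activation_duration_fraction < 1:
            raise ValueError("activation_duration_fraction must be in (0, 1)")
        if not 0 < self.activation_rise_fraction < 1:
            raise ValueError("activation_rise_fraction must be in (0, 1)")
        if self.v0 < 0:
            raise ValueError("unstressed volume v0 must be >= 0")
        if self.activation_delay < 0:
            raise ValueError("activation_delay must be >= 0")


@dataclass(frozen=True)
class CompartmentParams:
    """A passive RC vascular compartment.

    Pressure is ``(V - v_unstressed) / compliance``; outflow runs through
    ``r_out`` toward the downstream compartment.  Inertance is deliberately
    omitted: the study's metrics (PV-loop scalars, beat-averaged arterial
    indices) are insensitive to it and the cited base-model values for it are
    not available.
    """

    compliance: float
    r_out: float
    v_unstressed: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_finite(f.name, getattr(self, f.name))
        if self.compliance <= 0:
            raise ValueError("compliance must be > 0")
        if self.r_out <= 0:
            raise ValueError("r_out must be > 0")
        if self.v_unstressed < 0:
            raise ValueError("v_unstressed must be >= 0")


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameterization of the closed-loop circulation."""

    la: ChamberParams
    lv: ChamberParams
    ra: ChamberParams
    rv: ChamberParams
    aorta: CompartmentParams
    beds: tuple[CompartmentParams, ...]  # five, in BED_NAMES order
    systemic_veins: CompartmentParams
    thoracic_veins: CompartmentParams  # its r_out is the vena-caval occlusion site
    pulmonary_arteries: CompartmentParams
    pulmonary_veins: CompartmentParams
    r_mitral: float
    r_aortic: float
    r_tricuspid: float
    r_pulmonic: float
    #: Inertance of the aortic root (mmHg*s^2/mL).  Blood momentum through
    #: the aortic valve sustains ejection past peak elastance; the other
    #: valves are purely resistive.
    aortic_inertance: float
    heart_rate: float  # beats/min, right-atrial pacing rate
    total_blood_volume: float  # mL

    def __post_init__(self) -> None:
        if len(self.beds) != len(BED_NAMES):
            raise ValueError(f"expected {len(BED_NAMES)} beds, got {len(self.beds)}")
        for name in ("r_mitral", "r_aortic", "r_tricuspid", "r_pulmonic", "aortic_inertance"):
            value = getattr(self, name)
            _require_finite(name, value)
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be > 0")
        if self.total_blood_volume <= self.total_unstressed_volume:
            raise ValueError(
                "total_blood_volume must exceed the sum of unstressed volumes"
            )
        period = self.period
        for label, ch in (("la", self.la), ("lv", self.lv), ("ra", self.ra), ("rv", self.rv)):
            if ch.activation_delay + ch.activation_duration_fraction * period >= period:
                raise ValueError(f"{label}: activation window must end within the pacing period")

    # -- derived quantities -------------------------------------------------

    @property
    def period(self) -> float:
        """Pacing period in seconds."""
        return 60.0 / self.heart_rate

    @property
    def total_unstressed_volume(self) -> float:
        vol = self.la.v0 + self.lv.v0 + self.ra.v0 + self.rv.v0
        for c in self.compartments:
            vol += c.v_unstressed
        return vol

    @property
    def compartments(self) -> tuple[CompartmentParams, ...]:
        """All passive compartments in state-vector order."""
        return (
            self.aorta,
            *self.beds,
            self.systemic_veins,
            self.thoracic_veins,
            self.pulmonary_arteries,
            self.pulmonary_veins,
        )

    @property
    def total_arterial_compliance(self) -> float:
        """C_A: aortic plus peripheral-bed compliance (mL/mmHg)."""
        return self.aorta.compliance + sum(b.compliance for b in self.beds)

    @property
    def arterial_resistance(self) -> float:
        """Arterial part of R_T: effective proximal plus parallel bed resistance."""
        r_prox = self.aorta.r_out / len(self.beds)
        g_beds = sum(1.0 / b.r_out for b in self.beds)
        return r_prox + 1.0 / g_beds

    @property
    def venous_resistance(self) -> float:
        """Venous part of R_T (systemic plus thoracic vein outflow)."""
        return self.systemic_veins.r_out + self.thoracic_veins.r_out

    @property
    def total_systemic_resistance(self) -> float:
        """R_T: series resistance from the aortic root to the right atrium."""
        return self.arterial_resistance + self.venous_resistance


# ---------------------------------------------------------------------------
# Default parameter set
# ---------------------------------------------------------------------------

#: Fraction of total peripheral conductance carried by each bed
#: (splanchnic, extra-splanchnic, skeletal muscle, brain, coronary).
_BED_CONDUCTANCE_FRACTIONS = (0.30, 0.25, 0.20, 0.15, 0.10)

#: Fraction of total arterial (non-aortic) compliance per bed.
_BED_COMPLIANCE = (0.15, 0.12, 0.10, 0.05, 0.03)

_BED_UNSTRESSED = (170.0, 130.0, 110.0, 65.0, 35.0)

# Values of the three calibration knobs frozen from a run of
# calibrate_baseline against 120/80 mmHg and SV 46.5 mL at the normal
# compliance level (see analysis/01_calibrate_baseline.py).  The pressure
# targets are met within ~5 mmHg; stroke volume settles ~10 mL above its
# target because mean pressure and total resistance pin cardiac output.
_CALIBRATED_LV_EMAX = 2.5138622578125
_CALIBRATED_BLOOD_VOLUME = 4663.53759765625
_CALIBRATED_VENOUS_COMPLIANCE = 43.7050048828125


def default_parameters(
    c_a: float = 0.7,
    r_t: float = 1.28,
    heart_rate: float = 80.0,
) -> ModelParameters:
    """Build the default human-scale parameter set.

    The arterial side is constructed so that the derived total arterial
    compliance and total systemic resistance equal ``c_a`` and ``r_t``
    exactly (defaults: the normal stiffening level, C_A = 0.7 mL/mmHg and
    R_T = 1.28 mmHg*s/mL).  The three calibration knobs (LV peak elastance,
    total blood volume, systemic venous compliance) carry values frozen from
    a converged baseline calibration against 120/80 mmHg aortic pressure and
    a 46.5 mL stroke volume at 80 bpm.
    """
    aorta_c_fraction = 0.25 / 0.70  # proximal aorta's share of C_A
    aorta_c = c_a * aorta_c_fraction
    bed_c_total = c_a - aorta_c

    r_prox_branch = 0.06  # per-branch proximal aortic resistance
    r_venous = 0.045
    r_beds_parallel = r_t - r_venous - r_prox_branch / len(BED_NAMES)
    if r_beds_parallel <= 0:
        raise ValueError("r_t too small for the fixed proximal/venous resistances")

    bed_c_scale = bed_c_total / sum(_BED_COMPLIANCE)
    beds = tuple(
        CompartmentParams(
            compliance=c * bed_c_scale,
            r_out=r_beds_parallel / w,
            v_unstressed=v,
        )
        for c, w, v in zip(_BED_COMPLIANCE, _BED_CONDUCTANCE_FRACTIONS, _BED_UNSTRESSED)
    )

    return ModelParameters(
        la=ChamberParams(e_max=0.25, e_min=0.13, v0=10.0,
                         activation_duration_fraction=0.16, activation_delay=0.0),
        lv=ChamberParams(e_max=_CALIBRATED_LV_EMAX, e_min=0.055, v0=10.0,
                         activation_duration_fraction=0.84, activation_delay=0.04,
                         activation_rise_fraction=0.90),
        ra=ChamberParams(e_max=0.22, e_min=0.10, v0=10.0,
                         activation_duration_fraction=0.16, activation_delay=0.0),
        rv=ChamberParams(e_max=0.65, e_min=0.045, v0=10.0,
                         activation_duration_fraction=0.84, activation_delay=0.04,
                         activation_rise_fraction=0.90),
        aorta=CompartmentParams(compliance=aorta_c, r_out=r_prox_branch,
                                v_unstressed=280.0),
        beds=beds,
        systemic_veins=CompartmentParams(compliance=_CALIBRATED_VENOUS_COMPLIANCE,
                                         r_out=0.030, v_unstressed=2250.0),
        thoracic_veins=CompartmentParams(compliance=15.0, r_out=0.015,
                                         v_unstressed=280.0),
        pulmonary_arteries=CompartmentParams(compliance=4.5, r_out=0.08,
                                             v_unstressed=120.0),
        pulmonary_veins=CompartmentParams(compliance=8.0, r_out=0.010,
                                          v_unstressed=350.0),
        r_mitral=0.005,
        r_aortic=0.015,
        r_tricuspid=0.005,
        r_pulmonic=0.006,
        aortic_inertance=3.0e-4,
        heart_rate=heart_rate,
        total_blood_volume=_CALIBRATED_BLOOD_VOLUME,
    )


# ---------------------------------------------------------------------------
# Flat key-value parameter files (TOML dotted keys)
# ---------------------------------------------------------------------------

_CHAMBER_KEYS = ("e_max", "e_min", "v0", "activation_duration_fraction",
                 "activation_delay", "activation_rise_fraction")
_COMPARTMENT_KEYS = ("compliance", "r_out", "v_unstressed")
_SCALARS = ("r_mitral", "r_aortic", "r_tricuspid", "r_pulmonic",
            "aortic_inertance", "heart_rate", "total_blood_volume")
_CHAMBER_FIELDS = ("la", "lv", "ra", "rv")
_COMPARTMENT_FIELDS = ("aorta", "systemic_veins", "thoracic_veins",
                       "pulmonary_arteries", "pulmonary_veins")


def to_flat_dict(params: ModelParameters) -> dict[str, float]:
    """Flatten a parameter set to dotted ``section.key`` float entries."""
    out: dict[str, float] = {}
    for name in _CHAMBER_FIELDS:
        ch = getattr(params, name)
        for key in _CHAMBER_KEYS:
            out[f"{name}.{key}"] = getattr(ch, key)
    for name in _COMPARTMENT_FIELDS:
        comp = getattr(params, name)
        for key in _COMPARTMENT_KEYS:
            out[f"{name}.{key}"] = getattr(comp, key)
    for bed_name, bed in zip(BED_NAMES, params.beds):
        for key in _COMPARTMENT_KEYS:
            out[f"bed_{bed_name}.{key}"] = getattr(bed, key)
    for name in _SCALARS:
        out[name] = getattr(params, name)
    return out


def from_flat_dict(flat: dict[str, float]) -> ModelParameters:
    """Inverse of :func:`to_flat_dict`."""

    def chamber(name: str) -> ChamberParams:
        return ChamberParams(**{k: float(flat[f"{name}.{k}"]) for k in _CHAMBER_KEYS})

    def compartment(name: str) -> CompartmentParams:
        return CompartmentParams(**{k: float(flat[f"{name}.{k}"]) for k in _COMPARTMENT_KEYS})

    return ModelParameters(
        la=chamber("la"), lv=chamber("lv"), ra=chamber("ra"), rv=chamber("rv"),
        aorta=compartment("aorta"),
        beds=tuple(compartment(f"bed_{b}") for b in BED_NAMES),
        systemic_veins=compartment("systemic_veins"),
        thoracic_veins=compartment("thoracic_veins"),
        pulmonary_arteries=compartment("pulmonary_arteries"),
        pulmonary_veins=compartment("pulmonary_veins"),
        **{name: float(flat[name]) for name in _SCALARS},
    )


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as a flat ``key = value`` TOML file."""
    lines = ["# vvcsim model parameters (mmHg, mL, s)"]
    for key, value in to_flat_dict(params).items():
        lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _flatten(tree: dict, prefix: str = "") -> dict[str, float]:
    flat: dict[str, float] = {}
    for key, value in tree.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, prefix=f"{name}."))
        else:
            flat[name] = float(value)
    return flat


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a parameter set written by :func:`save_parameters`."""
    with open(path, "rb") as fh:
        tree = tomllib.load(fh)
    return from_flat_dict(_flatten(tree))
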