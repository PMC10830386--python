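"""Pressure-volume and arterial-dynamics analytics.

Per-beat scalars follow the standard PV-plane conventions: end-diastole at
maximum LV volume, end-systole at minimum LV volume (the upper-left corner
of the loop), stroke work as the signed area enclosed by the loop, and the
end-systolic pressure-volume relation (ESPVR) as an ordinary least-squares
line ``Pes = Ees * (ESV - V0)`` over the occlusion beats.

Arterial indices per beat:

* ``art_ca`` -- dynamic arterial compliance, SV / Pes (mL/mmHg)
* ``art_ea`` -- effective arterial elastance, Pes / SV (mmHg/mL)
* ``eadyn`` -- dynamic arterial elastance, PP / SV (dimensionless)

``art_ca`` and ``art_ea`` are mutual reciprocals by construction; the study
contrast is that they track preload during an occlusion while ``eadyn``
stays nearly constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model_core import SimulationTrace

__all__ = [
    "Beat",
    "BeatMetrics",
    "ESPVRFit",
    "ArterialMetrics",
    "RelationStats",
    "segment_beats",
    "beat_metrics",
    "fit_espvr",
    "pva",
    "mechanical_efficiency",
    "arterial_metrics",
    "relation_stats",
    "preload_sensitivity",
]


@dataclass
class Beat:
    """One cardiac cycle's aligned series, spanning one pacing interval."""

    time: np.ndarray
    lv_pressure: np.ndarray
    lv_volume: np.ndarray
    aortic_pressure: np.ndarray
    onset_time: float

    def __post_init__(self) -> None:
        n = len(self.time)
        if n == 0:
            raise ValueError("beat series must be non-empty")
        for name in ("lv_pressure", "lv_volume", "aortic_pressure"):
            if len(getattr(self, name)) != n:
                raise ValueError("beat series must share one length")


@dataclass
class BeatMetrics:
    """Per-beat PV scalars; ``pva``/``me`` are filled once an ESPVR is known."""

    edv: float  # end-diastolic volume, mL
    esv: float  # end-systolic volume, mL
    sv: float  # stroke volume, mL
    pes: float  # end-systolic LV pressure, mmHg
    edp: float  # end-diastolic LV pressure, mmHg
    pp: float  # aortic pulse pressure, mmHg
    dpdt_max: float  # peak dP/dt of LV pressure, mmHg/s
    sw: float  # stroke work, mmHg*mL
    onset_time: float
    ejecting: bool  # SV > 0
    pva: float | None = None  # pressure-volume area, mmHg*mL
    me: float | None = None  # mechanical efficiency, percent


@dataclass(frozen=True)
class ESPVRFit:
    """Linear end-systolic pressure-volume relation over occlusion beats."""

    ees: float  # slope, mmHg/mL
    v0: float  # volume-axis intercept, mL
    r_squared: float
    n_beats: int


@dataclass(frozen=True)
class ArterialMetrics:
    """Per-beat arterial indices; ``defined`` is False for non-ejecting beats."""

    art_ca: float
    art_ea: float
    eadyn: float
    defined: bool = True


@dataclass(frozen=True)
class RelationStats:
    """Shape statistics of a bivariate relation over occlusion beats."""

    slope: float
    intercept: float
    r_squared_linear: float
    curvature_index: float  # relative RMSE reduction of quadratic vs linear fit


# ---------------------------------------------------------------------------


def segment_beats(trace: SimulationTrace) -> list[Beat]:
    """Split a trace into complete beats at its pacing onsets.

    Each beat spans ``[onset_i, onset_{i+1}]`` inclusive of the closing
    boundary sample, so consecutive beats share exactly that sample and the
    PV loop of a steady-state beat closes on itself.
    """
    pacing = np.asarray(trace.pacing_times)
    if pacing.size < 2:
        raise ValueError("trace must contain at least two pacing times")
    if trace.time.size == 0:
        raise ValueError("empty trace")
    t_end = trace.time[-1]
    eps = 0.5 * trace.sample_interval
    beats: list[Beat] = []
    for t0, t1 in zip(pacing[:-1], pacing[1:]):
        if t1 > t_end + eps:
            break
        i0 = int(np.searchsorted(trace.time, t0 - eps))
        i1 = int(np.searchsorted(trace.time, t1 - eps))
        sl = slice(i0, min(i1 + 1, trace.time.size))
        beats.append(Beat(
            time=trace.time[sl],
            lv_pressure=trace.lv_pressure[sl],
            lv_volume=trace.lv_volume[sl],
            aortic_pressure=trace.aortic_pressure[sl],
            onset_time=float(t0),
        ))
    return beats


def _shoelace_area(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute area of the closed polygon with vertices (x_i, y_i)."""
    x2 = np.append(x, x[0])
    y2 = np.append(y, y[0])
    return 0.5 * abs(float(np.sum(x2[:-1] * y2[1:] - x2[1:] * y2[:-1])))


def beat_metrics(beat: Beat) -> BeatMetrics:
    """Compute the per-beat PV scalars from one segmented beat."""
    v = beat.lv_volume
    p = beat.lv_pressure
    # corner tie-breaks for polygonal loops with volume plateaus: end-systole
    # is the upper-left corner (max pressure at min volume), end-diastole the
    # lower-right corner (min pressure at max volume); both reduce to the
    # plain extrema on smooth simulated beats
    at_max = np.flatnonzero(v == v.max())
    at_min = np.flatnonzero(v == v.min())
    i_ed = int(at_max[np.argmin(p[at_max])])
    i_es = int(at_min[np.argmax(p[at_min])])
    edv = float(v[i_ed])
    esv = float(v[i_es])
    sv = edv - esv
    pes = float(p[i_es])
    edp = float(p[i_ed])
    pp = float(np.max(beat.aortic_pressure) - np.min(beat.aortic_pressure))
    if len(beat.time) >= 3:
        dpdt_max = float(np.max(np.gradient(p, beat.time)))
    else:
        dpdt_max = float("nan")
    sw = _shoelace_area(v, p)
    return BeatMetrics(
        edv=edv, esv=esv, sv=sv, pes=pes, edp=edp, pp=pp,
        dpdt_max=dpdt_max, sw=sw, onset_time=beat.onset_time,
        ejecting=sv > 0,
    )


def fit_espvr(points: Sequence[tuple[float, float]]) -> ESPVRFit:
    """Ordinary least-squares ESPVR over (ESV, Pes) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (ESV, Pes) points")
    esv, pes = pts[:, 0], pts[:, 1]
    if np.ptp(esv) == 0:
        raise ValueError("degenerate ESV spread")
    res = stats.linregress(esv, pes)
    if res.slope == 0:
        raise ValueError("zero ESPVR slope; volume intercept undefined")
    return ESPVRFit(
        ees=float(res.slope),
        v0=float(-res.intercept / res.slope),
        r_squared=float(res.rvalue**2),
        n_beats=int(pts.shape[0]),
    )


def pva(m: BeatMetrics, fit: ESPVRFit) -> float:
    """Pressure-volume area: stroke work plus the potential-energy triangle.

    The potential energy is the triangle between the ESPVR and the
    end-systolic point, ``0.5 * Pes * (ESV - V0)``, clamped at zero when the
    end-systolic volume falls below the fitted intercept.
    """
    pe = 0.5 * m.pes * max(m.esv - fit.v0, 0.0)
    return m.sw + pe


def mechanical_efficiency(sw: float, pva_value: float) -> float:
    """Mechanical efficiency ME = SW / PVA * 100 (percent)."""
    if pva_value <= 0:
        raise ValueError("PVA must be > 0")
    return 100.0 * sw / pva_value


def arterial_metrics(m: BeatMetrics) -> ArterialMetrics:
    """Per-beat arterial indices; undefined (NaN) for non-ejecting beats."""
    if m.sv <= 0 or m.pes <= 0:
        return ArterialMetrics(float("nan"), float("nan"), float("nan"), defined=False)
    return ArterialMetrics(
        art_ca=m.sv / m.pes,
        art_ea=m.pes / m.sv,
        eadyn=m.pp / m.sv,
        defined=True,
    )


def relation_stats(x: Sequence[float], y: Sequence[float]) -> RelationStats:
    """Linear fit plus a curvature index from a quadratic refit.

    ``curvature_index`` is the relative RMSE reduction obtained by allowing
    a quadratic term: 0 for an exactly linear relation, approaching 1 when
    the relation is strongly curved.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x spread")
    c1 = np.polyfit(x, y, 1)
    c2 = np.polyfit(x, y, 2)
    resid1 = y - np.polyval(c1, x)
    resid2 = y - np.polyval(c2, x)
    rmse1 = float(np.sqrt(np.mean(resid1**2)))
    rmse2 = float(np.sqrt(np.mean(resid2**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid1**2)) / ss_tot
    curvature = 0.0 if rmse1 == 0 else max(0.0, (rmse1 - rmse2) / rmse1)
    return RelationStats(
        slope=float(c1[0]), intercept=float(c1[1]),
        r_squared_linear=r2, curvature_index=curvature,
    )


def preload_sensitivity(metric_series: Sequence[float]) -> float:
    """Coefficient of variation (population std / mean) across beats.

    Used to quantify how strongly a per-beat index tracks the falling
    preload during an occlusion; a preload-insensitive index has CV near 0.
    """
    x = np.asarray(metric_series, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 beats")
    mean = float(x.mean())
    if mean <= 0:
        raise ValueError("mean must be > 0")
    return float(x.std(ddof=0)) / mean
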