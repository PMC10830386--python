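"""Run orchestration, CSV export, verification checks and figures.

Everything here is deterministic: two identical invocations write
byte-identical numeric artifacts.  Summary tables round volumes and
pressures to one decimal and derived indices to two, matching the usual
hemodynamic reporting convention; per-beat CSVs keep full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pv_analysis as pva
from .model_core import SimulationTrace
from .parameters import ModelParameters, default_parameters, load_parameters
from .protocols import (
    LEVEL_NAMES,
    ExperimentResult,
    VCOSpec,
    default_vco,
    run_experiment,
    standard_levels,
)

__all__ = ["RunConfig", "cmd_run", "cmd_verify", "cmd_figures", "coupling_statistics"]

TRACE_HEADER = ("time_s,lv_pressure_mmHg,lv_volume_mL,aortic_pressure_mmHg,"
                "aortic_inflow_mL_s,thoracic_vein_flow_mL_s")


def level_slug(name: str) -> str:
    return name.replace("%", "pct").lower()


@dataclass
class RunConfig:
    """Configuration of one full experiment run."""

    out_dir: Path = Path("results")
    params_path: Path | None = None  # None -> built-in calibrated defaults
    levels: tuple[str, ...] = LEVEL_NAMES
    vco: VCOSpec = field(default_factory=default_vco)
    figures: bool = True
    #: trace CSV covers [vco.start - trace_lead, vco.end] at full resolution
    trace_lead: float = 5.0

    def resolve_parameters(self) -> ModelParameters:
        if self.params_path is None:
            return default_parameters()
        return load_parameters(self.params_path)


def _fmt(x: float, nd: int) -> str:
    return f"{x:.{nd}f}"


def _beats_frame(result: ExperimentResult) -> pd.DataFrame:
    rows = []
    for i, (m, a) in enumerate(zip(result.beats, result.arterial)):
        rows.append(dict(
            level=result.level.name,
            beat_index=i,
            onset_time_s=m.onset_time,
            edv_mL=m.edv, esv_mL=m.esv, sv_mL=m.sv,
            pes_mmHg=m.pes, edp_mmHg=m.edp, pp_mmHg=m.pp,
            dpdt_max_mmHg_s=m.dpdt_max,
            sw_mmHg_mL=m.sw, pva_mmHg_mL=m.pva, me_pct=m.me,
            art_ca_mL_mmHg=a.art_ca, art_ea_mmHg_mL=a.art_ea, eadyn=a.eadyn,
            ejecting=m.ejecting,
            is_steady_state=i == result.steady_state_beat_index,
            in_vco_window=i in set(result.vco_beat_indices),
        ))
    return pd.DataFrame(rows)


def _write_trace_csv(trace: SimulationTrace, path: Path, t0: float, t1: float) -> None:
    sel = (trace.time >= t0 - 1e-9) & (trace.time <= t1 + 1e-9)
    frame = pd.DataFrame({
        "time_s": trace.time[sel],
        "lv_pressure_mmHg": trace.lv_pressure[sel],
        "lv_volume_mL": trace.lv_volume[sel],
        "aortic_pressure_mmHg": trace.aortic_pressure[sel],
        "aortic_inflow_mL_s": trace.aortic_inflow[sel],
        "thoracic_vein_flow_mL_s": trace.thoracic_vein_flow[sel],
    })
    frame.to_csv(path, index=False, float_format="%.6g")


def _summary_tables(results: list[ExperimentResult]) -> dict[str, pd.DataFrame]:
    wk_rows, lv_rows, me_rows = [], [], []
    for r in results:
        m = r.steady_state
        a = r.steady_state_arterial
        wk_rows.append(dict(
            level=r.level.name,
            c_a_mL_mmHg=r.level.c_a_target, r_t_mmHg_s_mL=r.level.r_t_target,
            sv_mL=_fmt(m.sv, 1), pp_mmHg=_fmt(m.pp, 1),
            art_ca_mL_mmHg=_fmt(a.art_ca, 2), art_ea_mmHg_mL=_fmt(a.art_ea, 2),
            eadyn=_fmt(a.eadyn, 2),
        ))
        lv_rows.append(dict(
            level=r.level.name,
            edv_mL=_fmt(m.edv, 1), esv_mL=_fmt(m.esv, 1),
            pes_mmHg=_fmt(m.pes, 1), edp_mmHg=_fmt(m.edp, 1),
            sw_mmHg_mL=_fmt(m.sw, 0),
            espvr_mmHg_mL=_fmt(r.espvr.ees, 2), me_pct=_fmt(m.me, 1),
        ))
        me_rows.append(dict(
            level=r.level.name,
            first_vco_beat_me_pct=_fmt(r.beats[r.vco_beat_indices[0]].me, 1),
            last_vco_beat_me_pct=_fmt(r.beats[r.vco_beat_indices[-1]].me, 1),
        ))
    return {
        "table_windkessel.csv": pd.DataFrame(wk_rows),
        "table_lv_function.csv": pd.DataFrame(lv_rows),
        "table_me_vco.csv": pd.DataFrame(me_rows),
    }


def cmd_run(config: RunConfig) -> list[ExperimentResult]:
    """Run the selected stiffening levels and write all artifacts.

    Per level: a trace CSV (occlusion window plus a pre-occlusion lead, at
    the trace sample interval), a pacing-times sidecar, and a per-beat
    metrics CSV.  Across levels: the three summary tables and a plain-text
    log of resolved parameters and solver settings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = config.resolve_parameters()
    wanted = [lv for lv in standard_levels() if lv.name in set(config.levels)]
    if not wanted:
        raise ValueError(f"no valid levels among {config.levels!r}")

    log_lines = [
        "vvcsim run log",
        f"levels: {', '.join(l.name for l in wanted)}",
        f"vco: start={config.vco.start_time}s ramp={config.vco.ramp_duration}s "
        f"hold={config.vco.hold_duration}s max_multiplier={config.vco.max_multiplier}",
        "integrator: RK4 dt=0.25 ms, output 1 ms",
        f"base C_A={base.total_arterial_compliance:.6f} mL/mmHg "
        f"R_T={base.total_systemic_resistance:.6f} mmHg*s/mL "
        f"HR={base.heart_rate} bpm TBV={base.total_blood_volume:.1f} mL",
        f"LV: e_max={base.lv.e_max:.6f} e_min={base.lv.e_min} v0={base.lv.v0}",
    ]

    results = []
    for level in wanted:
        r = run_experiment(base, level, config.vco)
        results.append(r)
        slug = level_slug(level.name)
        _write_trace_csv(r.trace, out / f"trace_{slug}.csv",
                         config.vco.start_time - config.trace_lead,
                         config.vco.end_time)
        pd.DataFrame({"pacing_time_s": r.trace.pacing_times}).to_csv(
            out / f"pacing_{slug}.csv", index=False, float_format="%.6g")
        # full round-trip precision: downstream identity checks (art_ca *
        # art_ea = 1) are asserted at 1e-9 on the re-read values
        _beats_frame(r).to_csv(out / f"beats_{slug}.csv", index=False)
        from .protocols import apply_level
        scaled = apply_level(base, level)
        log_lines.append(
            f"level {level.name}: derived C_A={scaled.total_arterial_compliance:.9f} "
            f"R_T={scaled.total_systemic_resistance:.9f}"
        )

    for name, frame in _summary_tables(results).items():
        frame.to_csv(out / name, index=False)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    if config.figures:
        cmd_figures(config)
    return results


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

def coupling_statistics(beats: pd.DataFrame) -> dict:
    """Preload-sensitivity and relation-shape statistics for one level.

    ``beats`` is one level's per-beat frame; statistics are computed over
    the occlusion (VCO window) beats.
    """
    vco = beats[beats.in_vco_window & beats.ejecting]
    stats = dict(
        cv_eadyn=pva.preload_sensitivity(vco.eadyn.to_numpy()),
        cv_art_ca=pva.preload_sensitivity(vco.art_ca_mL_mmHg.to_numpy()),
        cv_art_ea=pva.preload_sensitivity(vco.art_ea_mmHg_mL.to_numpy()),
    )
    pp_sv = pva.relation_stats(vco.sv_mL.to_numpy(), vco.pp_mmHg.to_numpy())
    pes_sv = pva.relation_stats(vco.sv_mL.to_numpy(), vco.pes_mmHg.to_numpy())
    pes_pp = pva.relation_stats(vco.pp_mmHg.to_numpy(), vco.pes_mmHg.to_numpy())
    stats.update(
        r2_pp_sv=pp_sv.r_squared_linear, curv_pp_sv=pp_sv.curvature_index,
        r2_pes_sv=pes_sv.r_squared_linear, curv_pes_sv=pes_sv.curvature_index,
        r2_pes_pp=pes_pp.r_squared_linear, curv_pes_pp=pes_pp.curvature_index,
    )
    return stats


def cmd_verify(config: RunConfig) -> tuple[bool, dict]:
    """Check identities and trend properties of a completed run.

    Returns ``(all_passed, report)`` and writes ``verify_report.json``.
    """
    out = Path(config.out_dir)
    checks: dict[str, dict] = {}

    def record(name: str, passed: bool, **info):
        checks[name] = dict(passed=bool(passed), **info)

    steady = {}
    for name in config.levels:
        slug = level_slug(name)
        path = out / f"beats_{slug}.csv"
        if not path.exists():
            record(f"artifacts_present[{name}]", False, missing=str(path))
            continue
        beats = pd.read_csv(path)
        record(f"artifacts_present[{name}]", True)
        ej = beats[beats.ejecting & beats.art_ca_mL_mmHg.notna()]
        prod = (ej.art_ca_mL_mmHg * ej.art_ea_mmHg_mL - 1.0).abs().max()
        record(f"art_ca_x_art_ea_is_1[{name}]", prod < 1e-9, max_abs_dev=float(prod))
        ratio = (ej.eadyn / ej.art_ea_mmHg_mL - ej.pp_mmHg / ej.pes_mmHg).abs().max()
        record(f"eadyn_over_art_ea_is_pp_over_pes[{name}]", ratio < 1e-9,
               max_abs_dev=float(ratio))
        vco = beats[beats.in_vco_window]
        edv = vco.edv_mL.to_numpy()
        record(f"edv_non_increasing_during_vco[{name}]",
               bool(np.all(np.diff(edv[1:]) <= 1e-9)))
        stats = coupling_statistics(beats)
        record(f"cv_eadyn_lt_cv_art_ca[{name}]",
               stats["cv_eadyn"] < stats["cv_art_ca"],
               cv_eadyn=stats["cv_eadyn"], cv_art_ca=stats["cv_art_ca"])
        record(f"pp_sv_linear[{name}]", stats["r2_pp_sv"] > 0.95,
               r_squared=stats["r2_pp_sv"])
        ss = beats[beats.is_steady_state]
        if len(ss) == 1:
            steady[name] = ss.iloc[0]

    if len(steady) == len(LEVEL_NAMES):
        ordered = [steady[n] for n in LEVEL_NAMES]
        for col, direction in (("pp_mmHg", 1), ("edv_mL", 1), ("pes_mmHg", 1),
                               ("sw_mmHg_mL", 1), ("art_ca_mL_mmHg", -1)):
            vals = np.array([row[col] for row in ordered])
            ok = bool(np.all(direction * np.diff(vals) > 0))
            record(f"steady_state_trend[{col}]", ok, values=vals.tolist())

    passed = all(c["passed"] for c in checks.values())
    (out / "verify_report.json").write_text(json.dumps(
        {"all_passed": passed, "checks": checks}, indent=2) + "\n")
    return passed, checks


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _load_level(out: Path, name: str):
    slug = level_slug(name)
    trace = pd.read_csv(out / f"trace_{slug}.csv")
    pacing = pd.read_csv(out / f"pacing_{slug}.csv").pacing_time_s.to_numpy()
    beats = pd.read_csv(out / f"beats_{slug}.csv")
    return trace, pacing, beats


def cmd_figures(config: RunConfig) -> list[Path]:
    """Render the eight standard figures from a completed run's CSVs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(config.out_dir)
    colors = plt.cm.viridis(np.linspace(0.0, 0.85, len(config.levels)))
    paths = []

    def save(fig, name):
        path = out / name
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)

    # 1: PV loops of the first occlusion beat per level
    fig, ax = plt.subplots(figsize=(6, 5))
    for color, name in zip(colors, config.levels):
        trace, pacing, beats = _load_level(out, name)
        onset = beats[beats.in_vco_window].onset_time_s.iloc[0]
        sel = (trace.time_s >= onset) & (trace.time_s <= onset + np.diff(pacing).mean())
        ax.plot(trace.lv_volume_mL[sel], trace.lv_pressure_mmHg[sel],
                color=color, label=name)
    ax.set_xlabel("LV volume (mL)")
    ax.set_ylabel("LV pressure (mmHg)")
    ax.set_title("First occlusion beat per compliance level")
    ax.legend()
    save(fig, "fig_pv_loops.png")

    # 2: ESPVR points and fits
    fig, ax = plt.subplots(figsize=(6, 5))
    for color, name in zip(colors, config.levels):
        _, _, beats = _load_level(out, name)
        vco = beats[beats.in_vco_window]
        ax.plot(vco.esv_mL, vco.pes_mmHg, "o", ms=3, color=color, label=name)
        coef = np.polyfit(vco.esv_mL, vco.pes_mmHg, 1)
        xs = np.linspace(vco.esv_mL.min(), vco.esv_mL.max(), 2)
        ax.plot(xs, np.polyval(coef, xs), "-", lw=1, color=color)
    ax.set_xlabel("End-systolic volume (mL)")
    ax.set_ylabel("End-systolic pressure (mmHg)")
    ax.set_title("ESPVR over the occlusion")
    ax.legend()
    save(fig, "fig_espvr.png")

    # 3-5: per-beat arterial indices during the occlusion
    for col, fname, label in (
        ("art_ca_mL_mmHg", "fig_art_ca.png", "Art-ca = SV/Pes (mL/mmHg)"),
        ("art_ea_mmHg_mL", "fig_art_ea.png", "Art-ea = Pes/SV (mmHg/mL)"),
        ("eadyn", "fig_eadyn.png", "Eadyn = PP/SV"),
    ):
        fig, ax = plt.subplots(figsize=(6, 4))
        for color, name in zip(colors, config.levels):
            _, _, beats = _load_level(out, name)
            vco = beats[beats.in_vco_window & beats.ejecting]
            ax.plot(range(len(vco)), vco[col], "o-", ms=3, color=color, label=name)
        ax.set_xlabel("Occlusion beat number")
        ax.set_ylabel(label)
        ax.legend()
        save(fig, fname)

    # 6-8: relation scatters over occlusion beats
    for xcol, ycol, fname, xl, yl in (
        ("sv_mL", "pes_mmHg", "fig_pes_sv.png", "SV (mL)", "Pes (mmHg)"),
        ("sv_mL", "pp_mmHg", "fig_pp_sv.png", "SV (mL)", "PP (mmHg)"),
        ("pp_mmHg", "pes_mmHg", "fig_pes_pp.png", "PP (mmHg)", "Pes (mmHg)"),
    ):
        fig, ax = plt.subplots(figsize=(6, 4))
        for color, name in zip(colors, config.levels):
            _, _, beats = _load_level(out, name)
            vco = beats[beats.in_vco_window & beats.ejecting]
            ax.plot(vco[xcol], vco[ycol], "o", ms=3, color=color, label=name)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.legend()
        save(fig, fname)

    return paths
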