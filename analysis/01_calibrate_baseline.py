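"""Calibrate the baseline circulation to 120/80 mmHg at 80 bpm.

The structural model (chambers, timing, circuit layout, normal-level
arterial parameters C_A = 0.7 mL/mmHg, R_T = 1.28 mmHg*s/mL) is fixed; a
deterministic coordinate search tunes LV peak elastance, total blood volume
and systemic venous compliance against last-beat aortic systolic/diastolic
pressure and stroke volume.  The pressure targets are met to within a few
mmHg; stroke volume settles ~10 mL above the 46.5 mL target because mean
aortic pressure and the prescribed total resistance pin cardiac output (an
internal inconsistency of the target set itself, reported as a residual).

Writes results/calibration.json and the calibrated flat parameter file
config/default_params.toml that the rest of the analysis consumes.
"""

import json
from pathlib import Path

from vvcsim import calibrate_baseline, default_parameters, save_parameters

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    res = calibrate_baseline(default_parameters())
    print(f"calibration: {res.n_evaluations} model evaluations, "
          f"converged={res.converged}")
    print(f"  systolic  {res.systolic:7.2f} mmHg (target 120, residual {res.residuals[0]:+.2f})")
    print(f"  diastolic {res.diastolic:7.2f} mmHg (target  80, residual {res.residuals[1]:+.2f})")
    print(f"  pulse pressure {res.systolic - res.diastolic:7.2f} mmHg")
    print(f"  stroke volume  {res.stroke_volume:7.2f} mL (target 46.5, residual {res.residuals[2]:+.2f})")
    print(f"  LV e_max {res.params.lv.e_max:.4f} mmHg/mL, blood volume "
          f"{res.params.total_blood_volume:.1f} mL, venous compliance "
          f"{res.params.systemic_veins.compliance:.1f} mL/mmHg")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "calibration.json").write_text(json.dumps(dict(
        converged=res.converged,
        n_evaluations=res.n_evaluations,
        systolic=res.systolic,
        diastolic=res.diastolic,
        pulse_pressure=res.systolic - res.diastolic,
        stroke_volume=res.stroke_volume,
        lv_e_max=res.params.lv.e_max,
        total_blood_volume=res.params.total_blood_volume,
        venous_compliance=res.params.systemic_veins.compliance,
    ), indent=2) + "\n")

    cfg = ROOT / "config"
    cfg.mkdir(exist_ok=True)
    save_parameters(res.params, cfg / "default_params.toml")
    print(f"wrote {cfg / 'default_params.toml'}")


if __name__ == "__main__":
    main()
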