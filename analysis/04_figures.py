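"""Re-render the eight standard figures from a completed run.

Figure rendering also happens at the end of 02_run_vco_grid.py; this
driver exists to regenerate figures without re-simulating.
"""

from pathlib import Path

from vvcsim.reporting import RunConfig, cmd_figures

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    for path in cmd_figures(RunConfig(out_dir=ROOT / "results")):
        print(path)


if __name__ == "__main__":
    main()
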