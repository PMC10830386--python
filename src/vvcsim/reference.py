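"""Published steady-state reference hemodynamics for the stiffening study.

Published first-occlusion-beat (steady-state) values for the five arterial
stiffening levels, from the canine-calibrated human-scale occlusion study
this model family targets.  They serve two purposes:

* the arterial-index identities (Art-ca = SV/Pes, Art-ea = Pes/SV,
  Eadyn = PP/SV) are checked against the reported two-decimal indices, and
* the simulated trends across levels are compared qualitatively (absolute
  values depend on the original study's unpublished base parameterization).

Units: volumes mL, pressures mmHg, stroke work mmHg*mL, ESPVR slope
mmHg/mL, mechanical efficiency percent.
"""

from __future__ import annotations

__all__ = ["REFERENCE_STEADY_STATE", "REFERENCE_ARTERIAL_INDICES"]

#: Reported steady-state LV-function and windkessel values per level.
REFERENCE_STEADY_STATE = {
    "Normal": dict(edv=100.5, esv=54.1, pes=81.7, edp=5.0, sw=3830.0,
                   ees=1.80, me=72.2, sv=46.5, pp=33.4),
    "90%": dict(edv=110.9, esv=61.8, pes=97.8, edp=5.9, sw=4802.0,
                ees=1.76, me=68.6, sv=49.1, pp=38.8),
    "80%": dict(edv=116.7, esv=65.9, pes=105.5, edp=6.3, sw=5359.0,
                ees=1.73, me=67.4, sv=50.8, pp=44.0),
    "60%": dict(edv=124.7, esv=71.4, pes=113.7, edp=7.0, sw=6150.0,
                ees=1.65, me=66.4, sv=53.3, pp=56.0),
    "Stiff": dict(edv=140.1, esv=87.4, pes=133.6, edp=8.4, sw=7313.0,
                  ees=1.44, me=60.8, sv=52.7, pp=106.6),
}

#: Reported two-decimal arterial indices per level (steady state).
REFERENCE_ARTERIAL_INDICES = {
    "Normal": dict(art_ca=0.57, art_ea=1.76, eadyn=0.72),
    "90%": dict(art_ca=0.50, art_ea=1.99, eadyn=0.79),
    "80%": dict(art_ca=0.48, art_ea=2.08, eadyn=0.87),
    "60%": dict(art_ca=0.47, art_ea=2.13, eadyn=1.05),
    "Stiff": dict(art_ca=0.39, art_ea=2.54, eadyn=2.02),
}
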