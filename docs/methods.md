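# Methods

## Model structure

The circulation is a closed loop of 14 volume states (mmHg, mL, s
throughout). Four cardiac chambers follow the time-varying-elastance law
P = E(t)·(V − V₀) with a squared-sine activation: E rises from E_min to
E_max as sin² over a rise phase and returns as cos² over a fall phase.
Activation is parameterized by its total duration (fraction of the pacing
period), its delay after the pacing stimulus, and the fraction of the window
spent rising; 0.5 gives the familiar symmetric squared half-sine, which the
atria use. Pacing is right-atrial at 80 beats/min with no reflex control of
any kind: autonomic efferents are frozen, equivalent to pharmacological
blockade during an invasive PV-loop study, so every beat-to-beat change is
purely mechanical.

Passive compartments are linear RC elements, P = (V − V_unstressed)/C, with
a single outflow resistance. The systemic arterial side is a proximal aorta
feeding five parallel peripheral beds whose outflows pool into systemic
veins, then thoracic veins, then the right atrium; each aorta→bed branch
carries the aorta's outflow resistance, so the effective proximal resistance
is that value divided by five. The pulmonary side is a two-compartment
(arterial/venous) circuit. Derived aggregates: total arterial compliance
C_A = C_aorta + ΣC_bed and total systemic resistance R_T = proximal +
parallel-bed + venous outflow resistances.

The mitral, tricuspid and pulmonic valves are ideal resistive diodes. The
aortic valve carries a 15th state, the root flow, governed by an inertance
(L·dQ/dt = P_lv − P_ao − R·Q, clamped at Q ≥ 0). This is deliberate: with a
single-peaked elastance and purely resistive valves, ejection terminates
within ~30 ms of peak elastance, capping the ejection phase near 0.2 s; at
the study's normal windkessel time constant (R_T·C_A ≈ 0.9 s) that forces a
pulse pressure near half the systolic pressure. Blood momentum in the root —
present in the model family this circuit descends from — plus a slow-rising
ventricular activation (rise fraction 0.9, duration fraction 0.84 of the
cycle) sustains ejection for ~0.35 s and yields the physiologic ~1/3
PP/systolic ratio. Every flow appears symmetrically in two volume
derivatives, so total blood volume is conserved exactly up to round-off.

## Integration and determinism

Fixed-step classical RK4 at dt = 0.25 ms, outputs resampled at 1 ms. The
aortic-valve flow state is clamped to zero after each step when momentum
would reverse it, and its momentum equation is frozen while the valve is
shut so stage evaluations cannot inject regurgitant flow. The kernel is
numba-compiled; there is no randomness anywhere on the simulation path, and
identical invocations are bit-identical. Halving dt changes last-beat stroke
volume by ~2·10⁻⁷ relative; an isolated RC compartment reproduces its
closed-form exponential discharge to <0.1% (both tested).

## Baseline parameterization and calibration

The default parameter set is constructed so the derived C_A and R_T equal
the normal level (0.7 mL/mmHg, 1.28 mmHg·s/mL) exactly, with bed compliances
and conductances split in physiologic proportions (splanchnic 30% of flow …
coronary 10%). Three knobs — LV peak elastance (bounded 1.2–3.0 mmHg/mL,
the physiologic adult range), total blood volume, and systemic venous
compliance — are tuned by a deterministic bounded coordinate search
(shrinking 9-point grids, 6 sweeps) against last-beat aortic systolic
120 mmHg, diastolic 80 mmHg and stroke volume 46.5 mL. The loss is a
weighted relative least squares with stroke volume down-weighted (weights
1, 1, 0.25): at R_T = 1.28 the three targets are mutually inconsistent,
because mean aortic pressure pins cardiac output (MAP ≈ CO·R_T + P_ra), so
pressures — the stated verification quantities — take precedence. The
shipped calibrated set achieves 118.5/75.4 mmHg (PP 43.1) with SV 56.2 mL;
the +10 mL stroke-volume residual is reported by the calibration routine,
which flags the result non-converged rather than silently accepting it.
The calibration's early-exit path returns a parameter set unchanged when
its output already sits within tolerance of the requested targets.

## Stiffening and occlusion protocols

Each of the five levels scales all six arterial compliances by a common
factor and the six arterial resistances by another, chosen so the derived
C_A and R_T hit the level targets exactly (venous and valve parameters are
never scaled). The stiff level uses C_A = 0.19 mL/mmHg. The occlusion ramps
the thoracic-vein outflow resistance linearly ×41 over 10 s after 180 s of
settling, then holds 5 s; the multiplier magnitude is a design choice (deep,
monotone preload fall within the 10–12 s occlusion window). Analysis windows:
the steady-state beat is the last beat paced before the ramp; the transient
window is the 20 beats whose pacing onset lies inside the ramp+hold.

## Analytics conventions

End-systole is the minimum-LV-volume sample (upper-left PV corner; on
polygonal fixture loops with volume plateaus, the maximum-pressure sample
among them), end-diastole the maximum-volume sample (minimum-pressure on
plateaus). Stroke work is the absolute shoelace area of the closed loop,
algebraically identical to the trapezoidal ∮P dV. The ESPVR is an ordinary
least-squares line of P_es on ESV over the transient-window beats only;
PVA adds the potential-energy triangle ½·P_es·(ESV − V₀) clamped at zero.
Preload sensitivity of a per-beat index is its coefficient of variation
(population standard deviation / mean) across the transient window.
Curvature of a bivariate relation is the relative RMSE reduction of a
quadratic versus a linear OLS fit. Non-ejecting beats are flagged and their
arterial indices reported as undefined. Summary tables round volumes and
pressures to one decimal and indices to two.

## Synthetic fixtures

The analytics are testable without the ODE model through polygonal PV loops
(rectangles, whose stroke work is exact polygon area), collinear or
seeded-gaussian end-systolic point sets, and concatenated fixture traces
that segment back to their generating loops bit-exactly. These fixtures
emulate the geometry of PV data, not solver noise or physiologic
variability; passing them validates the metric arithmetic, not the
hemodynamics.

## Design choices and known limitations

* **Reported absolute values are not reproduced.** The published experiment
  rests on a base parameterization that is not public; its printed tables
  are internally inconsistent with the printed R_T values taken literally
  (e.g. the stiff level's SV and pressures would require a mean aortic
  pressure near 260 mmHg at R_T = 3.66). This package fixes its own
  parameterization, applies the printed C_A/R_T levels literally, and
  reproduces directions and contrasts: EDV, P_es, PP, SW rising and Art-ca,
  ME falling with stiffness; Eadyn preload-insensitive relative to
  Art-ca/Art-ea; PP–SV linear; P_es–PP curved. At the stiff level the
  absolute pressures are consequently supraphysiologic (P_es ≈ 275 mmHg).
* **Fitted ESPVR slope does not decline toward the stiff level.** In a pure
  time-varying-elastance ventricle every occlusion beat closes the aortic
  valve at the same activation phase, so the fitted slope equals the
  closure-phase elastance (~96% of E_max here) at every level and even ticks
  up ~0.9% at the stiff level. The published mild decline (1.80 → 1.44)
  would require load-dependent relaxation, which elastance models exclude
  by construction. This limitation is asserted in the acceptance suite as a
  deliberately failing check rather than hidden.
* Reflexes, respiration, gas exchange and nonlinear compartment laws are out
  of scope; inertance exists only at the aortic root; valves never
  regurgitate.
* Simulated problem sizes: 195 s per level (240 settling beats + 20
  occlusion beats) at dt = 0.25 ms, five levels per grid; the calibration
  search evaluates ~150 candidate parameter sets at 60 s each.
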