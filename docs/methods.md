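# Methods

`cardioloop` couples a deterministic 0-D model of a bench circulation loop
(an atrioventricular–aortic hydraulic rig) to a clinical-style pulse-wave
analysis toolbox. This note records the model, its parameters, the
numerical choices, and what the synthetic data can and cannot stand in for.

## The closed-loop circuit model

The loop mirrors the bench rig it emulates: a compliant left-ventricular
(LV) sac squeezed by a piston pump, a prosthetic aortic valve, a
human-scale artificial aorta with its major branches, outlet units (a
half-filled air syringe plus a screw clamp) at every branch terminus, a
pair of air compliance chambers joined by a resistance valve, an open
venous reservoir whose height sets venous pressure, a compliant left
atrium (LA), and a mechanical mitral valve back into the LV.

**LV.** Time-varying elastance:
`P_lv = E(t)·(V − V0) + a·(exp(b·(V − V0)) − 1)`.
The activation `E(t) = E_min + s·(E_max − E_min)·e(t)` uses a smooth
two-phase cosine rise/decay over `systolic_fraction` of the cycle
(rise occupies 40 % of the activation window), so `E` and its first
derivative are continuous and periodic. The contractility scale `s`
multiplies the activation amplitude and therefore its slope. The
exponential term is the end-diastolic stiffening of a sac confined in a
rigid housing; without it, raising the venous reservoir inflates the
ventricle without bound. Defaults: `E_min = 0.06 mmHg/mL`,
`V0 = 10 mL`, `a = 0.03 mmHg`, `b = 0.035 /mL`, `systolic_fraction =
0.35`. `E_max` is the pump-drive knob; the preset table carries values
calibrated (by the built-in secant routine `calibrate_emax_for_co`) so
each scenario lands on its nominal cardiac output.

**Valves.** Smoothed diodes with a cracking pressure:
`q = (w/R)·ln(1 + exp((Δp − θ)/w))`, with `R` the open resistance, `w =
0.3 mmHg` the transition width and `θ = 0.8 mmHg` the opening threshold.
The softplus form guarantees strictly non-negative flow; the threshold
makes the diode effectively passive — without it the exponential tail
sustains a spurious ~0.1 L/min circulation around an unpowered loop,
with it an unpowered loop settles below 0.05 L/min.

**Aorta.** The mold geometry (segment lengths and inlet diameters, trunk
segments tapering linearly to the next segment's inlet) is discretised
into ~10 mm R-L-C compartments: `C = A·l/(ρc²)`, `L = ρ·l/A`,
`R = 8μl/(πr⁴)`. Two refinements matter in practice:

* *Oscillatory losses.* Steady Poiseuille resistance underestimates the
  dissipation of pulsatile flow at cardiac frequencies by an order of
  magnitude (Womersley numbers here are ~20–40, plus entrance and bend
  losses). Ladder resistances are scaled by `viscous_loss_multiplier =
  20`. Without it the tube rings for many cycles after each valve
  closure; series fluid resistance damps the low-frequency slosh while
  leaving the wave foot essentially undispersed.
* *Wall viscoelasticity.* Each compartment wall is a Voigt element: the
  node pressure seen by the links is `P + τ_w·dP/dt` with
  `τ_w = 2 ms` (a loss tangent of a few percent at pulse frequencies,
  typical of latex/silicone). This removes residual high-frequency
  ringing without measurably shifting foot-to-foot transit times.

**PWV/compliance reconciliation.** The fabricated aortas are specified by
both a pulse wave velocity and a statically measured compliance, and the
thin-tube relation `C = V/(ρc²)` cannot satisfy both (the tube volume is
~150 mL; the measured AC would require ~1.8 L at the nominal PWV). By
default every compartment compliance is rescaled by one factor so the
ladder sums exactly to the target AC, and the implied *effective* wave
speed `c_eff = PWV/√scale` is reported and used as the wave-transit
reference (3.4 m/s for the mid-range aorta). A `preserve_pwv` flag keeps
the nominal PWV instead and forgoes the AC match. Static inflation of the
sealed ladder returns the configured AC exactly (linear compartment law).

**Terminations and afterload.** Each terminal branch ends in a windkessel
outlet: the air syringe hangs off the terminal node through a short
coupling resistance (0.05 mmHg·s/mL) and the clamp drains the node into
chamber 1. Syringe compliances are sized so each terminus roughly matches
its branch's characteristic impedance at pulse frequencies — the
small-branch termini (renal, coronary, subclavian) would otherwise be
strong negative reflectors. Clamp resistances split the output in
physiological proportions (iliac 1.7, renal 2.4, subclavians 3–4,
coronary 12 mmHg·s/mL); `outlet_resistance_scale ≥ 1` models tightening
every clamp at once. Chamber compliances are 1 mL/mmHg each with
0.25 mmHg·s/mL between them and 0.12 mmHg·s/mL to the reservoir; the
configured DC resistance from root to reservoir is computed exactly by a
steady-flow network solve (`nominal_total_resistance`, ≈1.02 mmHg·s/mL ≈
17 mmHg·min/L at baseline).

**Venous side.** The reservoir is a constant-pressure node at
`ρ·g·venous_head` feeding the LA (C = 10 mL/mmHg) through 0.02 mmHg·s/mL.
Baseline head 0.128 m puts LVEDP at ≈7 mmHg; 0.045 m and 0.375 m give the
reduced (~2 mmHg) and raised (~26 mmHg) preload scenarios.

## Numerics

Fixed-step RK4 on the full state (LV and LA volumes, compartment
pressures, link flows, syringe and chamber pressures, and a bookkeeping
reservoir volume so total fluid volume is conserved identically). The
step starts from 0.1 ms and is automatically reduced until every
eigenvalue of the linear subsystem sits inside the RK4 stability region
(the stiffest poles live at the small-branch termini). The period is an
integer number of steps; traces are recorded at ~1 kHz. Periodic steady
state is declared when the cycle-to-cycle maximum pressure change at
every node falls below 0.5 mmHg (minimum 4, maximum 50 cycles); the
presets converge in 4–8 cycles, a couple of seconds each on one CPU.
Two runs with the same configuration are bit-identical.

## Analysis layer choices

* **Beat feet** use the intersecting-tangent rule: the tangent at the
  upstroke (least-squares over ±10 ms around the mid-amplitude crossing,
  after a 4th-order zero-phase 25 Hz Butterworth low-pass) intersected
  with the horizontal through the preceding minimum (median over ±15 ms).
  Feet are reported at sub-sample precision; beats whose length deviates
  more than 20 % from the median spacing are excluded from ensemble
  statistics. At 5 % pulse-pressure noise individual feet jitter by a few
  milliseconds; all downstream timing estimates take medians across beats.
* **LVEDP** is read at the end-diastolic plateau: walking back from the
  point of maximum upstroke slope to where the smoothed dP/dt falls below
  2 % of its peak. The raw tangent foot lands partway up the gentle
  early elastance rise and overestimates LVEDP by ~10 mmHg.
* **MAP** is canonically the trapezoidal time average over whole beats;
  the one-third rule `DBP + PP/3` is provided separately because the
  bench worked example is internally consistent under it. TPR is MAP/CO
  with venous pressure neglected, reproducing the printed arithmetic.
* **Augmentation index**: the inflection is the first (− to +) zero
  crossing of the smoothed second derivative after the maximum-slope
  point and before the systolic peak (type A). A late shoulder after the
  peak is accepted only as a complete inflection pair (up- and
  down-crossing), reported with the negative-AP convention as type C —
  a bare monotone decay (e.g. a Gaussian tail) stays undefined.
* **Impedance** uses the DFT of one beat-periodic window, harmonics 0–15
  (15 harmonics reconstruct ≥99 % of beat variance); harmonics with
  negligible flow power are flagged unreliable, never silently dropped.
  Harmonic 0 is mean pressure over mean flow and equals TPR.
* **Wave intensity** defaults to the time-normalised convention
  `(dP/dt)(dU/dt)` with 25 Hz-smoothed central differences; the literal
  per-sample `ΔP·ΔU` is retained (sampling-rate dependent). Peak
  labelling (Wf1/Wb/Wf2) uses a prominence floor of 0.5 % of max |dI|:
  with impedance-matched terminations the reflected and decompression
  peaks are genuinely small (≈1 % of Wf1), as expected for a well-matched
  afterload; the classic +,−,+ sequence is still resolved on every
  converged baseline run.
* **Foot-to-foot PWV** pairs each proximal foot with the next distal foot
  within the same beat and takes the median transit; sub-sample feet make
  constructed delays recover exactly. Transit below one sampling interval
  is reported as unresolvable, not extrapolated.

## What the generator does and does not emulate

It reproduces, per scenario, the qualitative bench findings: pulse
pressure falls with heart rate at matched output, rises monotonically
across the stiffness series, clamping raises mean pressure while output
falls (the pump is neither a flow nor a pressure source), low output
backs pressure up into the atrium, reservoir height sets LVEDP, pulse
pressure amplifies toward the abdominal tap, aortic dp/dt_max tracks
contractility, the dicrotic notch is present and diastolic aortic flow is
near zero. Baseline lands at CO ≈ 5 L/min, MAP ≈ 94 mmHg, TPR ≈ 19
mmHg·min/L, LVEDP ≈ 7 mmHg, SV ≈ 66 mL.

It does **not** emulate: 3-D flow (no PIV-comparable fields, no valve
fluid dynamics beyond a lumped diode), non-Newtonian rheology, the exact
piston displacement profile (the elastance surrogate has its own
waveform, so absolute pulse pressures and dp/dt magnitudes differ from
the bench numbers), reservoir-level dynamics (the constant-pressure
venous node understates the LVEDP rise at low output), or structural
remodeling. Passing the suite therefore certifies the analysis chain and
the model's response *directions and balances*, not bench-identical
waveform magnitudes.

## Known limitations

* Contractility scenarios change only the drive amplitude, so cardiac
  output drifts ~±15 % across them rather than being re-matched; the
  dp/dt ordering is unaffected.
* The effective wave speed under the AC-matched default is ~3–5 m/s,
  well below the nominal PWV of the stiff aortas; wave-transit
  quantities are therefore compared against `c_eff`, not the nominal
  PWV.
* The foot detector's per-foot noise robustness is a few milliseconds at
  5 % pulse-pressure noise; applications needing tighter feet should
  average more beats.
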