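# cardioloop

Closed-loop hemodynamics of the coupled left-atrium / left-ventricle /
aorta system, on your desk: a deterministic lumped-parameter (0-D)
simulator of a bench circulation rig — elastance-driven ventricular sac,
prosthetic one-way valves, a human-scale tapered aortic tree discretised
as an R-L-C transmission-line ladder, syringe-and-clamp outlet units,
paired air compliance chambers and a venous reservoir — paired with the
pulse-wave analysis toolbox used to characterise such rigs (and patients):

* per-beat indices: SBP/DBP/PP, time-averaged and one-third-rule MAP,
  form factor `FF = (MAP − DBP)/(SBP − DBP)`, augmentation index
  `AIx = 100·(SBP − Pi)/PP`, dp/dt_max, LVEDP, SV, CO,
  `TPR = MAP/CO`, static-inflation compliance;
* aortic input impedance `z(ω) = p(ω)/q(ω)` by beat-periodic DFT;
* wave intensity `dI = dP·dU` with forward/backward peak labelling
  (Wf1, Wb, Wf2);
* foot-to-foot pulse wave velocity by the intersecting-tangent rule.

It is intended for methods development and teaching: every analysis
routine can be exercised against a fully controlled, reproducible
synthetic circulation whose contractility, heart rate, preload, aortic
stiffness and peripheral resistance are independent knobs.

## Worked example

```python
import cardioloop as cl

res = cl.simulate(cl.make_preset("baseline"))   # HR 75, mid-range aorta
print(f"CO      {res.co_measured:.2f} L/min")
print(f"cycles  {res.cycles_run} (converged={res.converged})")

asc = res.records["ascending_aorta"]            # WaveformRecord
s = cl.summarize(asc, co_lmin=res.co_measured, hr_hint=75)
print(f"SBP/DBP {s.sbp:.1f}/{s.dbp:.1f} mmHg  MAP {s.map_timeavg:.2f}")
print(f"TPR     {s.tpr:.2f} mmHg·min/L   SV {s.sv:.0f} mL/beat")
print(f"LVEDP   {cl.summarize(res.records['LV'], hr_hint=75).lvedp:.1f} mmHg")
```

prints (to the displayed precision):

```
CO      4.98 L/min
cycles  6 (converged=True)
SBP/DBP 140.3/79.9 mmHg  MAP 94.37
TPR     18.94 mmHg·min/L   SV 67 mL/beat
LVEDP   7.1 mmHg
```

A healthy adult at rest: mean aortic pressure ~94 mmHg and total
peripheral resistance ~19 mmHg·min/L at 5 L/min output, end-diastolic
filling pressure ~7 mmHg. The stiffness (`aorta_1`…`aorta_8`), heart-rate
(`hr_50`…`hr_125`), output (`co_2`…`co_5`), preload, contractility and
clamping (`high_tpr`) presets move exactly one physiological knob each;
`cl.circuit_sim.PRESET_NAMES` lists them all.

The same pipeline is available from the shell:

```bash
cardioloop simulate --preset baseline --out run/
cardioloop analyze --pressure run/ascending_aorta.csv --out report.json
cardioloop pwv --prox run/ascending_aorta.csv \
               --dist run/abdominal_aorta.csv --distance 0.27
```

`simulate` writes one self-describing CSV per measurement site (LA, LV,
ascending aorta at 6 cm, abdominal aorta at 23 cm past the arch center)
plus run metadata; `analyze` emits a schema-validated JSON report with
full-precision values and 2-d.p. printed mirrors.

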