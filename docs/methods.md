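# Methods

## Model

`lvadsim` couples a subcellular contraction model to a closed-loop lumped
circulation through a Laplace-law ventricle, and adds an intra-aortic
rotary blood pump.  The state vector has 12 components: three troponin
pools and the cross-bridge length of the left-ventricular (LV) sarcomere,
seven compartment volumes, and the pump flow.

### Calcium transient

The LV is driven by a prescribed intracellular calcium waveform: a raised
cosine rising from the 0.1 μM diastolic level to Ca_max + 0.1 μM at
t = T₁, falling back by t = T₂, with T₁ = 40.6 ms and T₂ = 130.2 ms in a
0.8 s cycle.  After T₂ the concentration is zero (the literal piecewise
form).  A configuration flag (`calcium.literal_tail = false`, CLI
`--calcium-tail baseline`) instead holds the 0.1 μM baseline through
diastole, which makes the waveform continuous at T₂ — but with a sustained
0.1 μM the troponin scheme equilibrates with ≈ 1 μM of bound cross-bridges,
a diastolic tone of several kPa that keeps end-diastolic pressure above
20 mmHg, prevents relaxation and produces beat-to-beat alternans.  The
zero tail is therefore the default; the continuous variant is retained
only for sensitivity studies.

Disease states change Ca_max alone: 1.47 μM healthy, 0.54 μM heart
failure (HF), 0.8 μM HF with β-blocker.  The β-blockers represented
(e.g. bisoprolol, metoprolol) act through restored calcium cycling and are
assumed to have no peripheral vascular effect.

### Sarcomere

The four-state troponin scheme (free T, calcium-bound TCa,
force-generating TCa*, myosin-bound T*) follows the Negroni–Lascano
cardiac muscle model.  Attachment (Y₂) is modulated by a Gaussian filament
overlap factor exp(−r_curv (L − Lₐ)²); detachment gains a term
Y_d (dX/dt)² quadratic in the cross-bridge velocity; free troponin is the
algebraic closure [T] = T_t − [TCa] − [TCa*] − [T*], so total troponin is
conserved exactly.  dX/dt = B(L − X − h_c) is evaluated algebraically
inside the right-hand side (no numerical differencing), keeping the ODE a
pure function of state.  The printed rates Y₁ and Z₃ multiply a
concentration, so they are implemented as bimolecular rates (μM⁻¹ s⁻¹).

Active stress F_a = a_scale·([TCa*]+[T*])·(L−X); passive stress
F_p = −k_stiff·(1 − L/L₀), tensile above the slack length L₀ = 1.17 μm and
compressive (suction) below it.  The kinetic constants are the tabulated
Negroni–Lascano set (`params/sarcomere_constants.yaml`); the four
mechanical constants absent from that set are package choices:

| constant | units | value | origin |
|---|---|---|---|
| `l_a` | μm | 1.17 | maximal overlap at slack length |
| `r_curv` | μm⁻² | 5 | mild overlap curvature over the working range |
| `a_scale` | kPa μM⁻¹ μm⁻¹ | calibrated (~8.4·10³) | sets systolic stress |
| `k_stiff` | kPa | calibrated (~109) | sets end-diastolic stiffness |

### Ventricle

A thin-walled hemisphere of constant wall thickness h: V = (2/3)πR³ (the
simplest form consistent with a hemispherical chamber), L/L₀ = R/R₀ and
P = 2Fh/R.  Stress (kPa) converts to pressure (mmHg) with the fixed
factor 7.50062.  The kinetics need only the length L and the internally
computed dX/dt, so no dL/dt feeds back into the sarcomere; the chain-rule
helper dL/dt = (L₀/R₀)·dV/dt/(2πR²) is exposed for analysis.

### Circulation and pump

Elastic compartments obey P = (V − V₀)/C; the right ventricle is a
time-varying elastance E(t) = E_min + (E_max−E_min) sin²(πt/T_sys) with
T_sys = 0.3 s; valves are exact ideal diodes Q = max(ΔP, 0)/R evaluated
directly in the right-hand side.  No solver event handling or smoothing is
used: LSODA's step-size control resolves the C⁰ kinks robustly and steady
states converge in ~10–20 cycles, so the extra machinery was dropped.

The pump head curve (quadratic in speed ω, drooping in flow Q, with blood
inertance L_p = 0.2 mmHg per (L/min)/s) makes Q a state:
L_p dQ/dt = P_in + P_p(ω,Q) − P_out.  The speed unit follows the curve's
convention ("R/s"); its rev/s-vs-rad/s ambiguity is absorbed by the head
coefficients.  A rated `omega_limit` is carried in the parameter set but
not enforced.  **Attachment**: the device is an intra-aortic pump, so the
default attachment is *in series* between the aortic and arterial
compartments — raising speed lowers the pressure the LV ejects against
(aortic-valve flow and arterial pressure rise with support, peak LV
pressure falls) — with a ventricle-to-aorta `bypass` attachment available
in configuration.  The series choice is the only one under which
aortic-valve flow *increases* with support level, the signature of the
support-level experiment this package reproduces.

Speed modulation: `co_pulse` adds a mean-centred raised-cosine pulse of
width T₂ (130.2 ms) aligned with the calcium transient, scaled by
`modulation_fraction` (default 0.3); `counter_pulse` shifts the pulse by
half a cycle; the cycle-average speed equals `omega_mean` in every mode,
so modes differ only in phasing.

### Circulation parameters and calibration

The loop's compliances, resistances and the RV elastance were never
published; the shipped set (`params/default_params.json`) is versioned
data produced by `calibrate_baseline`: bounded Nelder–Mead (fixed start,
no stochastic restarts, hence bit-deterministic) minimising weighted
squared relative residuals of four waveform targets — healthy peak LVP
110 mmHg, aortic systolic/diastolic 95/70 mmHg, and unassisted-HF mean
aortic-valve flow 2.87 L/min — over a_scale, k_stiff, R₀, R_sys and the
aortic/arterial compliances.  The remaining constants are fixed
physiological choices made during model construction: venous and pulmonary
compliances and unstressed volumes in textbook ranges; mitral resistance
0.04 and pulmonary vascular resistance 0.18 mmHg·s/mL (≈ 3 Wood units,
consistent with HF with secondary pulmonary hypertension).  The elevated
pulmonary resistance matters mechanically: with a low value the LV's
diastolic suction drains the pulmonary veins at extreme support levels and
right-ventricular load stops growing with support, contrary to the
monotone right-heart loading this model family exhibits.

### Metrics

External work EW = 0.0022/T·∫P(t)Q(t)dt with P in mmHg and Q in L/min is
dimensionally exact watts (1 mmHg·L/min = 2.2·10⁻³ W).  LV EW pairs LV
pressure with aortic-valve outflow, RV EW pairs RV pressure with
pulmonary-valve outflow, pump power pairs head with pump flow;
BAI = W_pump/(W_pump + W_LV) (hydraulic powers; electrical pump power is
not modelled).  PR = (max−min)/mean of a pressure waveform; arterial PR is
read on the arterial compartment, systolic/diastolic on the aortic one.
PV-loop area (shoelace) cross-checks LV EW in the test suite as an
independent stroke-work computation.

Published EW magnitudes for this system family are several watts; with the
exact unit conversion the whole-body LV external work of a failing heart
is bounded well below that (mean LVP·CO ≲ 110 mmHg · 5 L/min ≈ 1.2 W), so
this package reports true watts and treats mode *orderings*, not EW
magnitudes, as the reproducible quantity.

### Experiment protocols

* **Support-level sweep**: unassisted HF baseline plus one converged run
  per BAI target (20–90 %), each found by bisection on mean speed
  (achieved BAI within ±0.005; BAI is monotone in speed over the bracket).
* **Mode comparison**: constant / co-pulse / counter-pulse each bisected
  to a cycle-mean arterial pressure of 98 mmHg (±0.5 mmHg).
* **Drug coupling**: the β-blocker (Ca_max 0.54 → 0.8 μM) is added at the
  *unchanged* tuned speed of the paired LVAD run, modelling drug
  initiation without re-tuning the pump.  Re-matching arterial pressure
  after the drug was evaluated and discarded: it degrades the volume
  unloading the drug is meant to show.

## Numerics

* Integrator: LSODA, rtol 1e-8, atol 1e-10, cycle-by-cycle over the 0.8 s
  period.
* Periodic steady state: maximum scaled change of the cycle-start state
  below 1e-4 (scales: 0.1 μM, 0.1 μm, 10–100 mL, 0.5 L/min); healthy and
  HF baselines converge in under 20 cycles, assisted runs in ~10 from a
  warm start.  Non-convergence flags the result rather than raising.
* Output grid: 1 ms (801 points per cycle); metrics use trapezoidal
  quadrature.  Metrics agree to ≪ 0.5 % between rtol 1e-8 and 1e-6 and
  between 1 ms and 0.5 ms grids (asserted in the suite).
* Degenerate inputs: LV volume is floored at 10⁻⁶ mL inside the RHS to
  keep the radius map defined; valve flows are exactly zero under reverse
  gradients; a pump bracket that cannot reach a BAI/MAP target raises a
  `BracketError` carrying the achievable range.
* Determinism: there is no random number generation anywhere in the
  model; bisection and Nelder–Mead use fixed starting points, so all
  outputs are bit-reproducible on a given platform.

Problem sizes: every reported quantity uses the full 12-state loop at the
1 ms output grid; the test suite's longest runs are the eight-level sweep
(nine converged steady states) and a 50-cycle conservation integration,
keeping the default suite around two minutes on one CPU.

## Limitations

* No baroreflex or autonomic control: mean arterial pressure rises
  unchecked with support level, and heart rate is fixed at 75 min⁻¹.
* The linear passive law gives strong diastolic suction at small volumes;
  there is no suction-prevention controller and no pericardium.
* The right ventricle is a simple time-varying elastance, not the
  multi-scale chain; its absolute work values are indicative only.
* Valves are resistive diodes without inertance or regurgitation.
* BAI uses hydraulic powers; device electrical power and efficiency are
  out of scope, so BAI values are not directly comparable to definitions
  based on motor power.
* Drug effects enter only through Ca_max; pharmacokinetics, heart-rate
  effects and remodelling dynamics are not modelled.
* Wall thickness is constant over the cycle (no incompressibility
  correction), and the hemispherical geometry ignores trabecular and
  fibre-orientation detail.
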