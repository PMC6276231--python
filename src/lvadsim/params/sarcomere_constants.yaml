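# Sarcomere / calcium kinetic constants of the contractile model.
# Provenance per constant:
#   NL96 = Negroni & Lascano (1996) four-state troponin / cross-bridge
#          cardiac muscle model, the source of the kinetic scheme.
#   cal  = not part of the tabulated kinetic set; shipped as a package
#          default exposed for calibration (see default_params.json for
#          the calibrated values actually used by the simulator).
calcium:
  t1: 40.6        # ms, time of the calcium peak (NL96-style transient fit)
  t2: 130.2       # ms, return of the transient to the diastolic level
  ca_max: 1.47    # μM, healthy peak amplitude above baseline
  baseline: 0.1   # μM, diastolic calcium floor
  period: 0.8     # s, cardiac cycle
sarcomere:
  y1: 39.0        # μM⁻¹ s⁻¹, T + Ca association (NL96)
  z1: 30.0        # s⁻¹, TCa dissociation (NL96)
  y2: 1.3         # s⁻¹, TCa → TCa* cross-bridge attachment (NL96)
  z2: 1.3         # s⁻¹, TCa* → TCa detachment (NL96)
  y3: 30.0        # s⁻¹, TCa* → T* calcium release (NL96)
  z3: 1560.0      # μM⁻¹ s⁻¹, T* + Ca → TCa* (NL96)
  y4: 40.0        # s⁻¹, T* detachment (NL96)
  yd: 8.0         # s μm⁻², velocity-dependent detachment (NL96)
  t_total: 70.0   # μM, total troponin concentration (NL96)
  b: 800.0        # s⁻¹, cross-bridge length relaxation rate (NL96)
  h_c: 0.005      # μm, equilibrium cross-bridge elongation (NL96)
  l_0: 1.17       # μm, slack half-sarcomere length (NL96)
  l_a: 1.17       # μm, maximal-overlap length (cal; NL96-style default)
  r_curv: 5.0     # μm⁻², overlap curvature (cal)
  a_scale: 8500.0 # kPa μM⁻¹ μm⁻¹, active stress scale (cal)
  k_stiff: 80.0   # kPa, passive stiffness (cal)
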