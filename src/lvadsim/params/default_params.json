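{
  "calcium": {
    "baseline": 0.1,
    "ca_max": 1.47,
    "literal_tail": true,
    "period": 0.8,
    "t1": 40.6,
    "t2": 130.2
  },
  "circulation": {
    "c_ao": 0.4424880710819623,
    "c_art": 1.5309341349654353,
    "c_pa": 4.0,
    "c_pu": 9.0,
    "c_vc": 40.0,
    "r_aortic": 0.045,
    "r_mitral": 0.04,
    "r_prox": 0.04,
    "r_pul": 0.18,
    "r_pulmonic": 0.006,
    "r_sys": 1.2999076497889832,
    "r_tricuspid": 0.024,
    "rv_e_max": 0.35,
    "rv_e_min": 0.045,
    "rv_t_sys": 0.3,
    "rv_v0": 10.0,
    "v0_ao": 70.0,
    "v0_art": 600.0,
    "v0_pa": 120.0,
    "v0_pu": 200.0,
    "v0_vc": 2800.0
  },
  "control": {
    "enabled": false,
    "mode": "constant",
    "modulation_fraction": 0.0,
    "omega_mean": 0.0,
    "phase": 0.0,
    "pulse_width": 0.1302
  },
  "geometry": {
    "l_0": 1.17,
    "r_0": 3.58866591333975,
    "stress_to_pressure": 7.50062,
    "wall_thickness": 1.0
  },
  "pump": {
    "attachment": "series",
    "flow_coeff_intercept": 0.58,
    "flow_coeff_slope": 0.086,
    "inertance": 0.2,
    "lin_coeff": 0.079,
    "offset": -15.5,
    "omega_limit": 300.0,
    "quad_coeff": 0.0115
  },
  "sarcomere": {
    "a_scale": 8356.81557325651,
    "b": 800.0,
    "h_c": 0.005,
    "k_stiff": 108.99582160093445,
    "l_0": 1.17,
    "l_a": 1.17,
    "r_curv": 5.0,
    "t_total": 70.0,
    "y1": 39.0,
    "y2": 1.3,
    "y3": 30.0,
    "y4": 40.0,
    "yd": 8.0,
    "z1": 30.0,
    "z2": 1.3,
    "z3": 1560.0
  },
  "solver": {
    "atol": 1e-10,
    "cycle_tol": 0.0001,
    "grid_dt": 0.001,
    "max_cycles": 200,
    "method": "LSODA",
    "rtol": 1e-08
  }
}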