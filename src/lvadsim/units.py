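"""Unit conversion constants.

Internal conventions: time s, pressure mmHg, volume mL, chamber flow mL/s,
pump flow L/min (the pump head curve is stated in those units), length μm,
concentration μM, myofilament stress kPa.
"""

MS_PER_S = 1000.0

#: mmHg per kPa
MMHG_PER_KPA = 7.50062

#: mL/s per L/min
MLS_PER_LMIN = 1000.0 / 60.0

#: watts per (mmHg · L/min) — hydraulic power conversion
WATT_PER_MMHG_LMIN = 0.0022
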