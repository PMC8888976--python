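"""Steady-state closed-loop simulation: ten cardiac cycles at 75 bpm.

Prints the calibrated baseline hemodynamics; the numbers should read like
an adult human at rest (aortic pressure ~120/80 mmHg, stroke volume
70-90 ml, cardiac output 5-6 L/min).
"""

import numpy as np

from cardiobcg import (SolverSettings, assemble_model, baseline_parameters,
                       simulate)

params = baseline_parameters()
trace = simulate(assemble_model(params), SolverSettings(horizon=13.0))

last = trace.time >= trace.time[-1] - params.activation.cycle_length
pao = trace.pressures["ascending_aorta"][last]
plv = trace.pressures["left_ventricle"][last]
vlv = trace.volumes["left_ventricle"][last]
sv = np.ptp(vlv)
hr = 60.0 / params.activation.cycle_length

print(f"aortic pressure : {pao.max():.0f}/{pao.min():.0f} mmHg")
print(f"peak LV pressure: {plv.max():.0f} mmHg")
print(f"LV EDV/ESV      : {vlv.max():.0f}/{vlv.min():.0f} ml")
print(f"stroke volume   : {sv:.0f} ml  ->  CO {sv * hr / 1000:.1f} L/min")
total = trace.total_volume()
print(f"blood volume conserved to {np.ptp(total) / total.mean():.1e} (relative)")
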