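"""Verification run for the shipped baseline parameter set.

Prints the hemodynamic summary the calibration targets: aortic pressure
near 120/80 mmHg, stroke volume 70-90 ml, cardiac output 5-6 L/min at
75 beats/min, plus the occlusion-derived contractility indices (ESPVR
slope and PRSW) at baseline and at a 50% systolic-elastance reduction.

Run from the repository root:  python scripts/calibrate_baseline.py
"""

import warnings

import numpy as np

from cardiobcg import (SolverSettings, assemble_model, baseline_parameters,
                       contractility_sweep, simulate)


def main():
    p = baseline_parameters()
    trace = simulate(assemble_model(p), SolverSettings(horizon=13.0))
    t = trace.time
    last = t >= t[-1] - p.activation.cycle_length
    pao = trace.pressures["ascending_aorta"][last]
    vlv = trace.volumes["left_ventricle"][last]
    sv = vlv.max() - vlv.min()
    hr = 60.0 / p.activation.cycle_length
    print("baseline hemodynamics (last steady cycle)")
    print(f"  aortic pressure   : {pao.max():6.1f} / {pao.min():5.1f} mmHg")
    print(f"  LV EDV / ESV      : {vlv.max():6.1f} / {vlv.min():5.1f} ml")
    print(f"  stroke volume     : {sv:6.1f} ml")
    print(f"  cardiac output    : {sv * hr / 1000:6.2f} L/min at {hr:.0f} bpm")
    total = trace.total_volume()
    print(f"  volume conservation: {np.ptp(total) / total.mean():.2e} relative")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = contractility_sweep(p, [0.0, 0.5])
    e0, e5 = tab["ees"].to_numpy()
    w0, w5 = tab["prsw"].to_numpy()
    print("occlusion contractility indices")
    print(f"  Ees  : {e0:5.3f} -> {e5:5.3f} mmHg/ml "
          f"({100 * (e0 - e5) / e0:4.1f}% decrease)")
    print(f"  PRSW : {w0:5.1f} -> {w5:5.1f} mmHg "
          f"({100 * (w0 - w5) / w0:4.1f}% decrease)")


if __name__ == "__main__":
    main()
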