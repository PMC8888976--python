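"""Model-predicted ballistocardiogram and its contractility trends.

Synthesizes the whole-body force waveform from the simulated compartment
volumes, then extracts the J peak (the dominant early-systolic positive
peak) for a range of systolic-elastance reductions.  A weaker ventricle
makes the J peak arrive later and smaller.
"""

import numpy as np

from cardiobcg import (BCGConfig, SolverSettings, assemble_model,
                       baseline_parameters, bcg_force, model_bcg_features,
                       reduce_systolic_elastance, simulate)

base = baseline_parameters()
print("reduction   J delay (ms)   J amplitude (10^4 dyne)")
for red in (0.0, 0.1, 0.3, 0.5):
    p = reduce_systolic_elastance(base, red)
    trace = simulate(assemble_model(p), SolverSettings(horizon=13.0))
    wave = bcg_force(trace, BCGConfig.from_model(p))
    feats = model_bcg_features(wave, trace.cycle_starts[2:-1])
    delay = np.mean([f[0] for f in feats]) * 1000
    amp = np.mean([f[1] for f in feats]) / 1e4
    print(f"   {red:3.0%}      {delay:6.1f}          {amp:6.2f}")
print("\nDelay increases and amplitude decreases monotonically with the "
      "contractility reduction — the waveform features track cardiac "
      "function without a catheter.")
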