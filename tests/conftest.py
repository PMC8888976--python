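"""Shared fixtures.

The occlusion and steady-state simulations are the expensive pieces
(seconds each), so they are run once per session and shared by the model,
P-V, BCG and acceptance tests.
"""

import warnings

import numpy as np
import pytest

from cardiobcg import (SolverSettings, assemble_model, baseline_parameters,
                       reduce_systolic_elastance, simulate)
from cardiobcg.params import OcclusionProtocol

REDUCTIONS = (0.0, 0.1, 0.3, 0.5)


@pytest.fixture(scope="session")
def baseline_params():
    return baseline_parameters()


@pytest.fixture(scope="session")
def baseline_trace(baseline_params):
    """Ten steady cycles (13 s horizon, first 5 s discarded)."""
    return simulate(assemble_model(baseline_params),
                    SolverSettings(horizon=13.0))


@pytest.fixture(scope="session")
def steady_traces(baseline_params):
    """Steady-state runs for each systolic-elastance reduction."""
    out = {}
    for red in REDUCTIONS:
        p = reduce_systolic_elastance(baseline_params, red)
        out[red] = simulate(assemble_model(p), SolverSettings(horizon=13.0))
    return out


@pytest.fixture(scope="session")
def occlusion_traces(baseline_params):
    """Caval-occlusion runs (40 s, occlusion 20-30 s) per reduction."""
    out = {}
    for red in REDUCTIONS:
        p = reduce_systolic_elastance(baseline_params, red)
        p.occlusion = OcclusionProtocol()
        out[red] = simulate(assemble_model(p), SolverSettings(horizon=40.0))
    return out


@pytest.fixture(scope="session")
def occlusion_fits(occlusion_traces):
    """ESPVR/PRSW fits on the occlusion-window beats of each run."""
    from cardiobcg.pv import fit_espvr, fit_prsw, segment_cycles
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for red, trace in occlusion_traces.items():
            cycles = segment_cycles(trace)
            window = (trace.params.occlusion.t_start,
                      trace.params.occlusion.t_end)
            out[red] = (fit_espvr(cycles, during=window),
                        fit_prsw(cycles, during=window))
    return out
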