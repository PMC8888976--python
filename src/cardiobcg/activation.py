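"""Normalized ventricular activation and elastance drivers.

The activation waveform a(t_m) multiplies both the isovolumic pressure
source and the systolic elastance increment of each ventricle.  It is
defined on the cycle-relative time t_m = mod(t, Tc) as a product of tanh
ramps, truncated to zero at the end of systole:

    a(t_m) = tanh(5*q*t_m) * [tanh(q*(t_m - Ta)) - tanh(q*(t_m - Tb))] / (2*alpha)
             for t_m < Ts,   0 otherwise.

With the baseline constants (Tc=0.8 s, Ts=0.34 s, Ta=0.08 s, Tb=0.45 s,
alpha=0.8218, q=2*pi) the peak equals 1 to within 1e-3; note the truncation
at Ts is a genuine jump (a(Ts-) ~ 0.93), which the integrator handles by
restarting at each discontinuity instant.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .params import ActivationParams, VentricleParams


def activation(tm, ap: ActivationParams):
    """Normalized activation a(t_m) for cycle-relative time ``tm``.

    ``tm`` may be a scalar or array; the caller reduces absolute time modulo
    the cycle length.  Returns values in [0, 1] (to normalization accuracy).
    """
    ap.validate()
    tm = np.asarray(tm, dtype=float)
    core = (np.tanh(5.0 * ap.q * tm)
            * (np.tanh(ap.q * (tm - ap.ramp_up))
               - np.tanh(ap.q * (tm - ap.ramp_down)))
            / (2.0 * ap.alpha))
    # small tolerance keeps samples landing exactly on the truncation
    # instant on the post-jump branch regardless of float-mod rounding
    out = np.where(tm < ap.systole_length - 1e-9, core, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def ventricular_drivers(t: float, vp: VentricleParams, ap: ActivationParams):
    """Isovolumic source pressure U(t) [mmHg] and elastance E(t) [mmHg/ml]
    at absolute time ``t`` for one ventricle."""
    tm = float(np.mod(t, ap.cycle_length))
    a = activation(tm, ap)
    return vp.u0 * a, vp.e_dia + vp.e_sys * a


def max_isolated_elastance(vp: VentricleParams, els_reduction: float = 0.0) -> float:
    """Maximum elastance of the isolated chamber, e_dia + (1-r)*e_sys.

    This characterizes the ventricle irrespective of its load; the coupled
    end-systolic elastance measured from P-V loops is lower.
    """
    if not 0.0 <= els_reduction <= 1.0:
        raise ConfigurationError("els_reduction must lie in [0, 1]")
    return vp.e_dia + (1.0 - els_reduction) * vp.e_sys
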