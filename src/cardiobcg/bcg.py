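"""Ballistocardiogram synthesis from simulated compartment volumes.

The whole-body reaction force along the head-foot axis follows from the
acceleration of the blood mass distribution:

    f_A(t) = rho_b * sum_k y_k * d2 V_k / dt2        [dyne]

over nine cardiovascular compartments (both ventricles, four aortic
segments, iliac, pulmonary and cerebral arteries), with y_k the signed
head-positive distance (cm) of compartment k from the plane of the heart
valves and rho_b the blood density (g/ml; ml = cm^3, so the units work
out to g*cm/s^2 = dyne).  Second derivatives are central differences on
the solver grid; the two boundary points are dropped, not extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError
from .model import SolutionTrace
from .params import BCG_COMPARTMENTS, ModelParameters

#: default signed head-positive distances (cm) from the valve plane
DEFAULT_Y_CM = {
    "left_ventricle": 0.0,
    "right_ventricle": 0.0,
    "ascending_aorta": 5.0,
    "aortic_arch": 10.0,
    "thoracic_aorta": -10.0,
    "abdominal_aorta": -25.0,
    "iliac": -40.0,
    "pulmonary": 5.0,
    "cerebral": 35.0,
}


@dataclass
class BCGConfig:
    """Blood density and the nine compartment distances for force synthesis."""

    rho_b: float = 1.05                       # g/ml
    compartments: tuple = BCG_COMPARTMENTS    # ordered, exactly nine
    y_cm: dict = field(default_factory=lambda: dict(DEFAULT_Y_CM))

    def validate(self) -> "BCGConfig":
        if self.rho_b <= 0:
            raise ConfigurationError("rho_b must be positive")
        if len(self.compartments) != 9:
            raise ConfigurationError(
                f"BCG synthesis uses exactly 9 compartments, got "
                f"{len(self.compartments)}")
        missing = [c for c in self.compartments if c not in self.y_cm]
        if missing:
            raise ConfigurationError(f"missing y_cm for {missing}")
        return self

    @classmethod
    def from_model(cls, params: ModelParameters) -> "BCGConfig":
        """Distances taken from the arterial-segment geometry where the
        model defines them; ventricles sit on the valve plane."""
        y = dict(DEFAULT_Y_CM)
        for seg in params.segments:
            if seg.id in y:
                y[seg.id] = seg.y_cm
        return cls(rho_b=params.rho_b, y_cm=y)


@dataclass
class BCGWaveform:
    time: np.ndarray    # s
    force: np.ndarray   # dyne


def bcg_force(trace: SolutionTrace, cfg: BCGConfig | None = None) -> BCGWaveform:
    """Synthesize the BCG force waveform from a solution trace."""
    cfg = (cfg or BCGConfig()).validate()
    t = np.asarray(trace.time, dtype=float)
    dt = np.diff(t)
    if dt.size < 2 or np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0] + 1e-12:
        raise DataError("BCG synthesis requires a uniform time grid")
    h = float(dt[0])
    total = None
    for comp in cfg.compartments:
        if comp not in trace.volumes:
            raise ConfigurationError(f"trace lacks volume of compartment {comp!r}")
        v = trace.volumes[comp]
        acc = (v[2:] - 2.0 * v[1:-1] + v[:-2]) / (h * h)   # central difference
        contrib = cfg.y_cm[comp] * acc
        total = contrib if total is None else total + contrib
    return BCGWaveform(time=t[1:-1], force=cfg.rho_b * total)


def model_bcg_features(w: BCGWaveform, systole_onsets,
                       window: float = 0.34):
    """Per-cycle J-peak delay and amplitude from a synthesized waveform.

    For each systole onset, the J peak is the maximum of the force within
    (onset, onset + window]; returns a list of (delay_s, amplitude_dyne).
    Cycles whose search window is empty are skipped with a warning.
    """
    out = []
    t, f = w.time, w.force
    for onset in np.asarray(systole_onsets, dtype=float):
        m = (t > onset) & (t <= onset + window)
        if not np.any(m):
            warnings.warn(f"empty J-peak window for onset {onset:g} s; "
                          "cycle skipped", stacklevel=2)
            continue
        i = int(np.argmax(f[m]))
        out.append((float(t[m][i] - onset), float(f[m][i])))
    return out
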