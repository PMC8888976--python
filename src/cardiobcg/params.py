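"""Parameter containers for the closed-loop cardiovascular model.

All hydraulic quantities use the clinical unit system: pressures in mmHg,
volumes in ml, time in s.  Resistances are therefore mmHg*s/ml, compliances
ml/mmHg, inertances mmHg*s^2/ml and the viscoelastic wall coefficient gamma
mmHg*s/ml.  Distances for the ballistocardiographic force synthesis are in
cm, signed positive toward the head.

Every container round-trips through plain dicts (and hence JSON); the
shipped ``baseline.param`` file mirrors :func:`baseline_parameters`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ConfigurationError

#: The nine compartments whose volume accelerations generate the BCG force.
BCG_COMPARTMENTS = (
    "left_ventricle",
    "right_ventricle",
    "ascending_aorta",
    "aortic_arch",
    "thoracic_aorta",
    "abdominal_aorta",
    "iliac",
    "pulmonary",
    "cerebral",
)

#: Arterial segment ids required for a well-posed closed loop.
REQUIRED_SEGMENTS = (
    "ascending_aorta",
    "aortic_arch",
    "thoracic_aorta",
    "abdominal_aorta",
    "iliac",
    "cerebral",
    "pulmonary",
)


@dataclass
class ActivationParams:
    """Timing constants of the normalized ventricular activation waveform.

    The activation a(t_m), with t_m = mod(t, cycle_length), rises from 0 at
    the cycle start, peaks at 1 and is truncated to 0 at the end of systole
    (t_m >= systole_length); ``alpha`` normalizes the peak to 1 and ``q`` is
    the rate constant of the tanh ramps.
    """

    cycle_length: float = 0.8       # Tc, s
    systole_length: float = 0.34    # Ts, s
    ramp_up: float = 0.08           # Ta, s
    ramp_down: float = 0.45         # Tb, s
    alpha: float = 0.8218           # peak-normalization constant
    q: float = 2.0 * math.pi        # rad/s

    def validate(self) -> "ActivationParams":
        if not (0.0 < self.ramp_up < self.systole_length < self.ramp_down
                < self.cycle_length):
            raise ConfigurationError(
                "activation timing must satisfy 0 < ramp_up < systole_length"
                " < ramp_down < cycle_length, got "
                f"Ta={self.ramp_up}, Ts={self.systole_length},"
                f" Tb={self.ramp_down}, Tc={self.cycle_length}")
        if self.alpha <= 0 or self.q <= 0:
            raise ConfigurationError("alpha and q must be positive")
        return self


@dataclass
class VentricleParams:
    """Time-varying elastance chamber with a series isovolumic source.

    Chamber pressure follows P = u0*a(t) + (e_dia + e_sys*a(t)) * (V - v_unstressed),
    with a(t) the normalized activation.  ``e_dia`` is the constant diastolic
    elastance, ``e_sys`` the systolic elastance increment and ``u0`` the
    reference peak isovolumic pressure.  ``r_in``/``r_out`` sit in series with
    the inflow/outflow valves and ``r_visc`` is a small internal viscous
    resistance added to the outflow path.
    """

    side: str                      # "left" | "right"
    e_dia: float                   # mmHg/ml
    e_sys: float                   # mmHg/ml
    u0: float                      # mmHg
    r_in: float = 0.008
    r_out: float = 0.008
    r_visc: float = 0.003
    k_ej: float = 0.0              # quadratic ejection loss, mmHg*s^2/ml^2
    v_unstressed: float = 10.0     # ml
    # exponential passive wall stiffness (in parallel with the elastance):
    # P_passive = passive_scale * exp((V - passive_knee)/passive_lambda)
    passive_scale: float = 0.0     # mmHg
    passive_knee: float = 150.0    # ml
    passive_lambda: float = 25.0   # ml

    def validate(self) -> "VentricleParams":
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"ventricle side must be left/right, got {self.side!r}")
        if min(self.e_dia, self.e_sys, self.u0) <= 0:
            raise ConfigurationError("e_dia, e_sys and u0 must be positive")
        if min(self.r_in, self.r_out, self.r_visc, self.k_ej) < 0:
            raise ConfigurationError("ventricular resistances must be >= 0")
        return self


@dataclass
class ArterialSegmentParams:
    """One arterial segment: series resistance + inertance feeding a
    (visco)elastic wall chamber that drains through a second resistance.

    Trans-wall pressure is (V - v_unstressed)/compliance + gamma*dV/dt; a
    nonzero gamma reproduces the pressure-volume hysteresis of arterial
    walls.  ``y_cm`` is the signed head-positive distance of the segment from
    the plane of the heart valves and only matters for BCG synthesis.
    """

    id: str
    ra: float                      # inflow resistance, mmHg*s/ml
    rb: float                      # outflow resistance, mmHg*s/ml
    inertance: float               # mmHg*s^2/ml
    compliance: float              # ml/mmHg
    gamma: float                   # viscoelastic coefficient, mmHg*s/ml
    y_cm: float                    # signed distance from the valve plane
    v_unstressed: float            # ml

    def validate(self) -> "ArterialSegmentParams":
        if self.compliance <= 0:
            raise ConfigurationError(f"segment {self.id}: compliance must be > 0")
        if self.inertance < 0 or self.gamma < 0:
            raise ConfigurationError(f"segment {self.id}: inertance and gamma must be >= 0")
        if min(self.ra, self.rb) < 0:
            raise ConfigurationError(f"segment {self.id}: resistances must be >= 0")
        return self


@dataclass
class LumpedCompartmentParams:
    """Simple elastic compartment draining through ``r_out``."""

    compliance: float              # ml/mmHg
    v_unstressed: float            # ml
    r_out: float = 0.0             # mmHg*s/ml

    def validate(self) -> "LumpedCompartmentParams":
        if self.compliance <= 0:
            raise ConfigurationError("compartment compliance must be > 0")
        if self.r_out < 0 or self.v_unstressed < 0:
            raise ConfigurationError("compartment r_out and v_unstressed must be >= 0")
        return self


@dataclass
class OcclusionProtocol:
    """Transient caval occlusion: venous return to the right ventricle is
    interrupted during [t_start, t_end] and diverted into a storage
    compliance that discharges back into the venous line afterwards."""

    t_start: float = 20.0          # s
    t_end: float = 30.0            # s
    c_store: float = 10.0          # ml/mmHg

    def validate(self) -> "OcclusionProtocol":
        if not self.t_start < self.t_end:
            raise ConfigurationError("occlusion requires t_start < t_end")
        if self.c_store <= 0:
            raise ConfigurationError("c_store must be > 0")
        return self


@dataclass
class SolverSettings:
    """Integration controls.

    ``discard`` seconds are removed from the head of the trace (numerical
    start-up transient); the retained grid is uniform with step ``dt_out``.
    """

    rtol: float = 1e-6
    atol: float = 1e-6
    dt_out: float = 0.001          # s
    horizon: float = 13.0          # s
    discard: float = 5.0           # s

    def validate(self) -> "SolverSettings":
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigurationError("tolerances must be > 0")
        if self.dt_out <= 0:
            raise ConfigurationError("dt_out must be > 0")
        if not self.discard < self.horizon:
            raise ConfigurationError("discard must be smaller than horizon")
        return self


@dataclass
class ModelParameters:
    """Complete element-value set for the closed loop."""

    activation: ActivationParams = field(default_factory=ActivationParams)
    left: VentricleParams = field(default_factory=lambda: VentricleParams(
        side="left", e_dia=0.04, e_sys=1.375, u0=50.0,
        r_in=0.008, r_out=0.008, r_visc=0.02, k_ej=1e-4,
        passive_scale=5.0, passive_knee=150.0, passive_lambda=25.0))
    right: VentricleParams = field(default_factory=lambda: VentricleParams(
        side="right", e_dia=0.01, e_sys=0.23, u0=24.0,
        r_in=0.02, r_out=0.02, r_visc=0.01, k_ej=3e-5,
        passive_scale=2.0, passive_knee=180.0, passive_lambda=30.0))
    segments: list[ArterialSegmentParams] = field(default_factory=list)
    peripheral: LumpedCompartmentParams = field(default_factory=lambda:
        LumpedCompartmentParams(compliance=2.5, v_unstressed=250.0, r_out=0.15))
    veins: LumpedCompartmentParams = field(default_factory=lambda:
        LumpedCompartmentParams(compliance=18.0, v_unstressed=2000.0, r_out=0.02))
    pulmonary_veins: LumpedCompartmentParams = field(default_factory=lambda:
        LumpedCompartmentParams(compliance=80.0, v_unstressed=250.0, r_out=0.0))
    total_blood_volume: float = 4100.0   # ml
    rho_b: float = 1.05                  # g/ml
    store_resistance: float = 0.05       # coupling of the occlusion reservoir
    occlusion: OcclusionProtocol | None = None

    def segment(self, seg_id: str) -> ArterialSegmentParams:
        for seg in self.segments:
            if seg.id == seg_id:
                return seg
        raise ConfigurationError(f"missing arterial segment {seg_id!r}")

    def validate(self) -> "ModelParameters":
        self.activation.validate()
        self.left.validate()
        self.right.validate()
        if self.left.side != "left" or self.right.side != "right":
            raise ConfigurationError("ventricle sides are swapped")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate arterial segment ids")
        for seg in self.segments:
            seg.validate()
        for comp in (self.peripheral, self.veins, self.pulmonary_veins):
            comp.validate()
        if self.total_blood_volume <= 0 or self.rho_b <= 0:
            raise ConfigurationError("total_blood_volume and rho_b must be > 0")
        if self.store_resistance <= 0:
            raise ConfigurationError("store_resistance must be > 0")
        if self.occlusion is not None:
            self.occlusion.validate()
        return self

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        d["activation"] = ActivationParams(**d["activation"])
        d["left"] = VentricleParams(**d["left"])
        d["right"] = VentricleParams(**d["right"])
        d["segments"] = [ArterialSegmentParams(**s) for s in d["segments"]]
        for key in ("peripheral", "veins", "pulmonary_veins"):
            d[key] = LumpedCompartmentParams(**d[key])
        if d.get("occlusion") is not None:
            d["occlusion"] = OcclusionProtocol(**d["occlusion"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


def baseline_segments() -> list[ArterialSegmentParams]:
    """Default arterial tree (adult human scale, head-positive y)."""
    return [
        ArterialSegmentParams("ascending_aorta", ra=0.0, rb=0.010,
                              inertance=0.0, compliance=0.35, gamma=0.0,
                              y_cm=5.0, v_unstressed=25.0),
        ArterialSegmentParams("aortic_arch", ra=0.012, rb=0.012,
                              inertance=5e-4, compliance=0.42, gamma=0.02,
                              y_cm=10.0, v_unstressed=20.0),
        ArterialSegmentParams("thoracic_aorta", ra=0.012, rb=0.012,
                              inertance=8e-4, compliance=0.49, gamma=0.02,
                              y_cm=-10.0, v_unstressed=60.0),
        ArterialSegmentParams("abdominal_aorta", ra=0.015, rb=0.015,
                              inertance=1e-3, compliance=0.35, gamma=0.03,
                              y_cm=-25.0, v_unstressed=40.0),
        ArterialSegmentParams("iliac", ra=0.020, rb=0.85,
                              inertance=1.5e-3, compliance=0.28, gamma=0.04,
                              y_cm=-40.0, v_unstressed=50.0),
        ArterialSegmentParams("cerebral", ra=6.0, rb=1.0,
                              inertance=0.0, compliance=0.10, gamma=0.0,
                              y_cm=35.0, v_unstressed=30.0),
        ArterialSegmentParams("pulmonary", ra=0.0, rb=0.06,
                              inertance=0.0, compliance=4.0, gamma=0.0,
                              y_cm=5.0, v_unstressed=60.0),
    ]


def baseline_parameters(occlusion: bool = False) -> ModelParameters:
    """The documented default parameter set.

    Ventricular elastance/timing constants are the published baseline; the
    remaining element values are this package's calibration, chosen to give
    adult-human hemodynamics at 75 beats/min (aortic pressure near 120/80
    mmHg, stroke volume 70-90 ml, cardiac output 5-6 L/min) — see
    scripts/calibrate_baseline.py for the verification run.
    """
    p = ModelParameters(segments=baseline_segments())
    if occlusion:
        p.occlusion = OcclusionProtocol()
    return p.validate()


def reduce_systolic_elastance(params: ModelParameters,
                              reduction: float) -> ModelParameters:
    """Return a copy with the LV systolic elastance increment reduced by the
    given fraction (0 = baseline, 0.5 = half)."""
    if not 0.0 <= reduction <= 1.0:
        raise ConfigurationError("els reduction must lie in [0, 1]")
    d = params.to_dict()
    out = ModelParameters.from_dict(d)
    out.left.e_sys = params.left.e_sys * (1.0 - reduction)
    return out
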