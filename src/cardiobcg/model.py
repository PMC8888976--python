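"""Closed-loop lumped-parameter cardiovascular simulator.

The circulation is a hydraulic network solved as an ODE system whose states
are compartment volumes plus the inductor flows of the aortic segments:

    left ventricle -> ascending aorta -> aortic arch -> (cerebral branch)
    -> thoracic aorta -> abdominal aorta -> iliac -> systemic peripheral
    -> systemic veins -> right ventricle -> pulmonary arteries ->
    pulmonary veins -> left ventricle

Heart valves are ideal diodes with a small series resistance: a valve
carries flow only when the upstream pressure exceeds the downstream one
(flow = max(dP, 0)/R), which keeps the right-hand side continuous while
preserving ideal-switch semantics.  Viscoelastic arterial walls use
trans-wall pressure (V - Vu)/C + gamma*dV/dt; the implied algebraic
couplings reduce to closed-form scalar solves for this topology.

The caval-occlusion protocol interrupts venous return to the right
ventricle during [t_start, t_end]; venous blood accumulates in a storage
compliance C_store that stays coupled to the venous line through a small
resistance and therefore discharges again once the occlusion is released.

The activation waveform is discontinuous at the end of systole, so the
integrator is restarted at every cycle start and every end-of-systole
instant (and at the occlusion boundaries) instead of smoothing the jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .activation import activation
from .errors import AssemblyError, ConfigurationError, NumericalError
from .params import (ModelParameters, OcclusionProtocol, REQUIRED_SEGMENTS,
                     SolverSettings)

#: state vector layout: 13 volumes then 4 inductor flows
STATE_NAMES = (
    "V_left_ventricle", "V_right_ventricle", "V_ascending_aorta",
    "V_aortic_arch", "V_thoracic_aorta", "V_abdominal_aorta", "V_iliac",
    "V_cerebral", "V_pulmonary", "V_pulmonary_veins", "V_peripheral",
    "V_veins", "V_store",
    "Q_aortic_arch", "Q_thoracic_aorta", "Q_abdominal_aorta", "Q_iliac",
)

VOLUME_NAMES = tuple(n[2:] for n in STATE_NAMES[:13])

#: ventricular ejection tapers linearly to zero between FLOOR+TAPER and FLOOR (ml)
EJECTION_FLOOR = 2.0
EJECTION_TAPER = 8.0


def _passive(v, vp):
    """Exponential passive wall stress in parallel with the elastance
    element; negligible at operating volumes, it limits over-distension
    the way the real end-diastolic P-V relationship does."""
    if vp.passive_scale == 0.0:
        return 0.0
    return vp.passive_scale * np.exp((v - vp.passive_knee) / vp.passive_lambda)


def _ejection_flow(dp, vp):
    """Ventricular outflow through the series valve resistance plus the
    internal linear + quadratic (orifice-type) ejection loss:
    dp = (r_out + r_visc)*q + k_ej*q^2, conducting only for dp > 0."""
    dp = np.maximum(dp, 0.0)
    r = vp.r_out + vp.r_visc
    if vp.k_ej == 0.0:
        return dp / r
    return (np.sqrt(r * r + 4.0 * vp.k_ej * dp) - r) / (2.0 * vp.k_ej)


class ModelSystem:
    """Assembled equation set + discontinuity schedule for one parameter set."""

    def __init__(self, params: ModelParameters):
        params.validate()
        for seg_id in REQUIRED_SEGMENTS:
            try:
                params.segment(seg_id)
            except ConfigurationError as exc:
                raise AssemblyError(str(exc)) from None
        if params.segment("ascending_aorta").gamma != 0.0:
            raise AssemblyError(
                "ascending_aorta is the valve-fed chamber and must have gamma=0")
        for seg_id in ("cerebral", "pulmonary"):
            seg = params.segment(seg_id)
            if seg.inertance != 0.0 or seg.gamma != 0.0:
                raise AssemblyError(f"{seg_id} is a resistive-elastic branch; "
                                    "inertance and gamma must be 0")
        for seg_id in ("aortic_arch", "thoracic_aorta", "abdominal_aorta", "iliac"):
            if params.segment(seg_id).inertance <= 0.0:
                raise AssemblyError(f"{seg_id} requires a positive inertance")
        self.params = params

    # ------------------------------------------------------------ topology
    @property
    def has_occlusion(self) -> bool:
        return self.params.occlusion is not None

    @property
    def bcg_state_names(self) -> tuple:
        """The nine volume states entering the BCG force synthesis."""
        return STATE_NAMES[:9]

    def event_times(self, horizon: float) -> list:
        """Instants where the right-hand side is discontinuous (activation
        truncation, cycle restarts, occlusion boundaries)."""
        p = self.params
        tc, ts = p.activation.cycle_length, p.activation.systole_length
        times = set()
        k = 0
        while k * tc < horizon:
            times.add(k * tc)
            if k * tc + ts < horizon:
                times.add(k * tc + ts)
            k += 1
        if p.occlusion is not None:
            for t in (p.occlusion.t_start, p.occlusion.t_end):
                if 0.0 < t < horizon:
                    times.add(t)
        return sorted(times)

    # -------------------------------------------------------------- states
    def initial_state(self) -> np.ndarray:
        """Distribute the total blood volume over the compartments at
        physiological starting pressures; the venous reservoir absorbs the
        remainder (start-up transients are discarded by the solver)."""
        p = self.params
        start_p = {"ascending_aorta": 85.0, "aortic_arch": 85.0,
                   "thoracic_aorta": 85.0, "abdominal_aorta": 85.0,
                   "iliac": 85.0, "cerebral": 80.0, "pulmonary": 15.0}
        y = np.zeros(len(STATE_NAMES))
        y[0] = p.left.v_unstressed + 120.0    # LV near end-diastole
        y[1] = p.right.v_unstressed + 120.0
        for i, name in enumerate(VOLUME_NAMES[2:9], start=2):
            seg = p.segment(name)
            y[i] = seg.v_unstressed + seg.compliance * start_p[name]
        y[9] = p.pulmonary_veins.v_unstressed + p.pulmonary_veins.compliance * 8.0
        y[10] = p.peripheral.v_unstressed + p.peripheral.compliance * 18.0
        rest = float(np.sum(y[:11]))
        avail = p.total_blood_volume - rest
        c_sv, vu_sv = p.veins.compliance, p.veins.v_unstressed
        if p.occlusion is not None:
            # storage reservoir pre-charged to the venous pressure
            c_st = p.occlusion.c_store
            v_sv = (avail + (c_st / c_sv) * vu_sv) / (1.0 + c_st / c_sv)
            y[11] = v_sv
            y[12] = avail - v_sv
        else:
            y[11] = avail
            y[12] = 0.0
        if y[11] <= vu_sv:
            raise ConfigurationError(
                "total_blood_volume too small: venous reservoir would start "
                "below its unstressed volume")
        return y

    # ------------------------------------------------------------ dynamics
    def dynamics(self, t, y):
        """Time derivative and algebraic observables.

        Works elementwise: ``t`` scalar with ``y`` shape (17,), or ``t``
        shape (N,) with ``y`` shape (17, N).  Returns (dydt, aux) where aux
        maps observable names to values.
        """
        p = self.params
        ap = p.activation
        asc = p.segment("ascending_aorta")
        arch = p.segment("aortic_arch")
        thor = p.segment("thoracic_aorta")
        abd = p.segment("abdominal_aorta")
        ili = p.segment("iliac")
        cer = p.segment("cerebral")
        pul = p.segment("pulmonary")

        (v_lv, v_rv, v_ao, v_arch, v_thor, v_abd, v_ili, v_cer, v_pa,
         v_pvn, v_sp, v_sv, v_st, q_arch, q_thor, q_abd, q_ili) = y

        tm = np.mod(t, ap.cycle_length)
        a = activation(tm, ap)
        # elastance-branch (source) pressures; the chamber node adds the
        # internal viscous drop r_visc * dV/dt, so ejecting pressure is
        # lower than the isovolumic pressure at the same volume
        pe_lv = (p.left.u0 * a
                 + (p.left.e_dia + p.left.e_sys * a) * (v_lv - p.left.v_unstressed)
                 + _passive(v_lv, p.left))
        pe_rv = (p.right.u0 * a
                 + (p.right.e_dia + p.right.e_sys * a) * (v_rv - p.right.v_unstressed)
                 + _passive(v_rv, p.right))

        p_ao = (v_ao - asc.v_unstressed) / asc.compliance
        p_cer = (v_cer - cer.v_unstressed) / cer.compliance
        p_pa = (v_pa - pul.v_unstressed) / pul.compliance
        p_pvn = (v_pvn - p.pulmonary_veins.v_unstressed) / p.pulmonary_veins.compliance
        p_sp = (v_sp - p.peripheral.v_unstressed) / p.peripheral.compliance
        p_sv = (v_sv - p.veins.v_unstressed) / p.veins.compliance

        # valves: ideal diodes with small series resistance.  Ejection is
        # tapered smoothly to zero as a chamber approaches complete
        # emptying (a ventricle cannot eject blood it does not contain;
        # the isovolumic source term alone would otherwise drive volumes
        # negative under extreme preload reduction).
        guard_lv = np.clip((v_lv - EJECTION_FLOOR) / EJECTION_TAPER, 0.0, 1.0)
        guard_rv = np.clip((v_rv - EJECTION_FLOOR) / EJECTION_TAPER, 0.0, 1.0)
        q_mitral = np.maximum(p_pvn - pe_lv, 0.0) / p.left.r_in
        q_aortic = guard_lv * _ejection_flow(pe_lv - p_ao, p.left)
        q_pulm_valve = guard_rv * _ejection_flow(pe_rv - p_pa, p.right)
        # chamber (measured) pressures: the internal ejection loss makes
        # ejecting pressure lower than isovolumic pressure at the same volume
        p_lv = pe_lv - p.left.r_visc * q_aortic - p.left.k_ej * q_aortic ** 2
        p_rv = pe_rv - p.right.r_visc * q_pulm_valve - p.right.k_ej * q_pulm_valve ** 2

        # viscoelastic wall pressures; the dV/dt terms resolve in closed form
        g = arch.gamma / cer.ra
        p_arch = ((v_arch - arch.v_unstressed) / arch.compliance
                  + arch.gamma * (q_arch - q_thor) + g * p_cer) / (1.0 + g)
        q_cer_in = (p_arch - p_cer) / cer.ra
        p_thor = (v_thor - thor.v_unstressed) / thor.compliance + thor.gamma * (q_thor - q_abd)
        p_abd = (v_abd - abd.v_unstressed) / abd.compliance + abd.gamma * (q_abd - q_ili)
        g = ili.gamma / ili.rb
        p_ili = ((v_ili - ili.v_unstressed) / ili.compliance
                 + ili.gamma * q_ili + g * p_sp) / (1.0 + g)
        q_ili_out = (p_ili - p_sp) / ili.rb

        q_cer_out = (p_cer - p_sv) / cer.rb
        q_sp_out = (p_sp - p_sv) / p.peripheral.r_out
        q_pp = (p_pa - p_pvn) / pul.rb

        r_fill_rv = p.veins.r_out + p.right.r_in
        if p.occlusion is not None:
            occ = p.occlusion
            open_path = np.logical_or(t < occ.t_start, t >= occ.t_end)
            q_venous = np.where(
                open_path,
                np.maximum(p_sv - pe_rv, 0.0) / r_fill_rv,
                0.0)
            p_st = v_st / occ.c_store
            q_store = (p_sv - p_st) / p.store_resistance
        else:
            q_venous = np.maximum(p_sv - pe_rv, 0.0) / r_fill_rv
            q_store = np.zeros_like(q_venous)

        dq_arch = (p_ao - (asc.rb + arch.ra) * q_arch - p_arch) / arch.inertance
        dq_thor = (p_arch - (arch.rb + thor.ra) * q_thor - p_thor) / thor.inertance
        dq_abd = (p_thor - (thor.rb + abd.ra) * q_abd - p_abd) / abd.inertance
        dq_ili = (p_abd - (abd.rb + ili.ra) * q_ili - p_ili) / ili.inertance

        dydt = np.array([
            q_mitral - q_aortic,                 # LV
            q_venous - q_pulm_valve,             # RV
            q_aortic - q_arch,                   # ascending aorta
            q_arch - q_thor - q_cer_in,          # aortic arch
            q_thor - q_abd,                      # thoracic aorta
            q_abd - q_ili,                       # abdominal aorta
            q_ili - q_ili_out,                   # iliac
            q_cer_in - q_cer_out,                # cerebral
            q_pulm_valve - q_pp,                 # pulmonary arteries
            q_pp - q_mitral,                     # pulmonary veins
            q_ili_out - q_sp_out,                # peripheral
            q_sp_out + q_cer_out - q_venous - q_store,   # systemic veins
            q_store,                             # occlusion reservoir
            dq_arch, dq_thor, dq_abd, dq_ili,
        ])
        aux = {
            "P_left_ventricle": p_lv, "P_right_ventricle": p_rv,
            "P_ascending_aorta": p_ao, "P_aortic_arch": p_arch,
            "P_thoracic_aorta": p_thor, "P_abdominal_aorta": p_abd,
            "P_iliac": p_ili, "P_cerebral": p_cer, "P_pulmonary": p_pa,
            "P_pulmonary_veins": p_pvn, "P_peripheral": p_sp, "P_veins": p_sv,
            "Q_mitral": q_mitral, "Q_aortic": q_aortic,
            "Q_tricuspid": q_venous, "Q_pulmonic": q_pulm_valve,
            "Q_store": q_store, "activation": a,
        }
        return dydt, aux

    def rhs(self, t, y):
        return self.dynamics(t, y)[0]


@dataclass
class SolutionTrace:
    """Uniform-grid solution of one simulation run."""

    time: np.ndarray                       # s
    volumes: dict = field(default_factory=dict)     # ml, per compartment
    pressures: dict = field(default_factory=dict)   # mmHg, per compartment
    flows: dict = field(default_factory=dict)       # ml/s, named paths
    valve_open: dict = field(default_factory=dict)  # bool arrays
    cycle_starts: np.ndarray | None = None          # s, activation onsets
    params: ModelParameters | None = None

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def total_volume(self) -> np.ndarray:
        return np.sum([v for v in self.volumes.values()], axis=0)

    def to_frame(self):
        """Long header / wide columns DataFrame (time_s, V_* _ml, P_* _mmHg, Q_* _ml_s)."""
        import pandas as pd
        cols = {"time_s": self.time}
        for k, v in self.volumes.items():
            cols[f"V_{k}_ml"] = v
        for k, v in self.pressures.items():
            cols[f"P_{k}_mmHg"] = v
        for k, v in self.flows.items():
            cols[f"Q_{k}_ml_s"] = v
        return pd.DataFrame(cols)


def assemble_model(params: ModelParameters) -> ModelSystem:
    """Validate the parameter set and build the equation system."""
    return ModelSystem(params)


def apply_occlusion(system: ModelSystem,
                    protocol: OcclusionProtocol) -> ModelSystem:
    """Return a new system with the caval-occlusion protocol installed."""
    if system.has_occlusion:
        raise ConfigurationError("system already carries an occlusion protocol")
    d = system.params.to_dict()
    params = ModelParameters.from_dict(d)
    params.occlusion = protocol.validate()
    return ModelSystem(params)


def simulate(system: ModelSystem,
             settings: SolverSettings | None = None) -> SolutionTrace:
    """Integrate the closed loop and return the retained uniform-grid trace.

    The integration restarts at every discontinuity instant; the first
    ``settings.discard`` seconds are removed from the output.
    """
    settings = (settings or SolverSettings()).validate()
    p = system.params
    horizon, dt = settings.horizon, settings.dt_out
    n_grid = int(round(horizon / dt))
    grid = np.arange(n_grid + 1) * dt

    bounds = [t for t in system.event_times(horizon) if t < horizon]
    if not bounds or bounds[0] > 0.0:
        bounds.insert(0, 0.0)
    bounds.append(horizon)

    y = system.initial_state()
    times = [0.0]
    states = [y.copy()]
    eps = 1e-12
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        mask = (grid > t0 + eps) & (grid <= t1 + eps)
        t_eval = grid[mask]
        keep = np.ones(t_eval.size, dtype=bool)
        if t_eval.size == 0 or abs(t_eval[-1] - t1) > eps:
            t_eval = np.append(t_eval, t1)
            keep = np.append(keep, False)
        sol = solve_ivp(system.rhs, (t0, t1), y, method="LSODA",
                        rtol=settings.rtol, atol=settings.atol,
                        t_eval=t_eval, first_step=min(1e-4, t1 - t0))
        if not sol.success:
            last = sol.t[-1] if sol.t.size else t0
            raise NumericalError(
                f"integration failed in [{t0:g}, {t1:g}] s; last accepted "
                f"time {last:g} s: {sol.message}")
        y = sol.y[:, -1].copy()
        times.extend(sol.t[keep])
        states.extend(sol.y[:, keep].T)

    t_all = np.asarray(times)
    y_all = np.asarray(states).T            # (17, N)
    retain = t_all >= settings.discard - eps
    t_ret = t_all[retain]
    y_ret = y_all[:, retain]

    _, aux = system.dynamics(t_ret, y_ret)
    volumes = {name: y_ret[i] for i, name in enumerate(VOLUME_NAMES)}
    if p.occlusion is None:
        volumes.pop("store")
    pressures = {k[2:]: np.asarray(v) for k, v in aux.items() if k.startswith("P_")}
    flows = {
        "mitral": np.asarray(aux["Q_mitral"]),
        "aortic": np.asarray(aux["Q_aortic"]),
        "tricuspid": np.asarray(aux["Q_tricuspid"]),
        "pulmonic": np.asarray(aux["Q_pulmonic"]),
        "aortic_arch": y_ret[13], "thoracic_aorta": y_ret[14],
        "abdominal_aorta": y_ret[15], "iliac": y_ret[16],
    }
    valve_open = {k: np.asarray(aux[f"Q_{k}"]) > 0.0
                  for k in ("mitral", "aortic", "tricuspid", "pulmonic")}

    tc = p.activation.cycle_length
    k0 = int(np.ceil((t_ret[0] - eps) / tc))
    k1 = int(np.floor((t_ret[-1] + eps) / tc))
    cycle_starts = np.arange(k0, k1 + 1) * tc

    return SolutionTrace(time=t_ret, volumes=volumes, pressures=pressures,
                         flows=flows, valve_open=valve_open,
                         cycle_starts=cycle_starts, params=p)
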