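"""Pressure-volume loop analytics: beat segmentation, end-systole
detection, ESPVR and preload-recruitable stroke work fits.

Contractility indices follow the standard catheterization conventions:
end systole is the instant of maximal pressure/volume ratio within a beat,
the ESPVR slope (Ees, mmHg/ml) is the ordinary-least-squares line through
the end-systolic points of beats acquired under varying preload, stroke
work (SW, mmHg*ml) is the area of the P-V loop, and PRSW (mmHg) is the
OLS slope of SW against end-diastolic volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, FitError
from .model import SolutionTrace
from .params import ModelParameters, OcclusionProtocol, SolverSettings

#: end-systole is searched in the leading fraction of each cycle to avoid
#: spurious late-diastolic ratio artifacts
ES_SEARCH_FRACTION = 0.9


@dataclass
class PVCycle:
    """One cardiac cycle of LV pressure and volume."""

    time: np.ndarray       # s
    pressure: np.ndarray   # mmHg
    volume: np.ndarray     # ml
    index: int = 0

    def __post_init__(self):
        if not (len(self.time) == len(self.pressure) == len(self.volume)):
            raise DataError("cycle arrays must have equal length")
        if len(self.time) < 10:
            raise DataError("cycle must contain at least 10 samples")

    @property
    def edv(self) -> float:
        """End-diastolic volume: the maximum volume over the cycle."""
        return float(np.max(self.volume))

    @property
    def start(self) -> float:
        return float(self.time[0])


@dataclass
class ESPVRFit:
    slope: float           # Ees, mmHg/ml
    v_intercept: float     # V0, ml (volume-axis intercept)
    n_points: int
    r_squared: float


@dataclass
class PRSWFit:
    slope: float           # PRSW, mmHg
    intercept: float       # mmHg*ml
    n_points: int
    r_squared: float


def segment_cycles(trace, cycle_starts=None) -> list:
    """Split an LV pressure/volume series into complete cardiac cycles.

    ``trace`` is either a :class:`SolutionTrace` (cycle starts taken from
    the activation onsets it records) or a tuple ``(time, pressure, volume)``
    of arrays, in which case ``cycle_starts`` must be given or is derived
    from successive volume maxima.  A trailing partial cycle is discarded.
    """
    if isinstance(trace, SolutionTrace):
        t = trace.time
        pres = trace.pressures["left_ventricle"]
        vol = trace.volumes["left_ventricle"]
        if cycle_starts is None:
            cycle_starts = trace.cycle_starts
    else:
        t, pres, vol = (np.asarray(x, dtype=float) for x in trace)
        if cycle_starts is None:
            cycle_starts = _starts_from_volume_maxima(t, vol)
    cycle_starts = np.asarray(cycle_starts, dtype=float)
    cycles = []
    for i in range(len(cycle_starts) - 1):
        m = (t >= cycle_starts[i] - 1e-12) & (t < cycle_starts[i + 1] - 1e-12)
        if np.count_nonzero(m) >= 10:
            cycles.append(PVCycle(t[m], pres[m], vol[m], index=i))
    if not cycles:
        raise DataError("series does not cover one complete cardiac cycle")
    return cycles


def _starts_from_volume_maxima(t, vol):
    from scipy.signal import find_peaks
    dt = float(np.median(np.diff(t)))
    span = vol.max() - vol.min()
    peaks, _ = find_peaks(vol, prominence=0.2 * span,
                          distance=max(2, int(0.2 / dt)))
    if len(peaks) < 2:
        raise DataError("fewer than two end-diastolic maxima found")
    return t[peaks]


def end_systolic_point(cycle: PVCycle, v_offset: float = 0.0,
                       search_fraction: float = ES_SEARCH_FRACTION):
    """End-systolic (volume, pressure) at the maximum of P/(V - v_offset).

    The search is limited to the leading ``search_fraction`` of the cycle;
    ties resolve to the earliest sample.  ``v_offset`` subtracts an
    unstressed-volume convention from the denominator only; the returned
    volume is on the input scale.
    """
    n = max(2, int(search_fraction * len(cycle.volume)))
    v = cycle.volume[:n] - v_offset
    if np.any(v <= 0):
        raise DataError("non-positive volume sample in end-systole search")
    ratio = cycle.pressure[:n] / v
    i = int(np.argmax(ratio))
    return float(cycle.volume[i]), float(cycle.pressure[i])


def stroke_work(cycle: PVCycle) -> float:
    """Loop area |contour integral of P dV| via the shoelace rule (mmHg*ml).

    Orientation independent.  An open loop whose endpoint gap exceeds 5% of
    the volume range triggers a warning; the loop is then closed by joining
    the endpoints.
    """
    v, p = cycle.volume, cycle.pressure
    vspan = np.ptp(v)
    gap = np.hypot(v[-1] - v[0], p[-1] - p[0])
    if vspan > 0 and abs(v[-1] - v[0]) > 0.05 * vspan:
        warnings.warn("open P-V loop: endpoint gap exceeds 5% of the volume "
                      "range; closing the loop by joining endpoints",
                      stacklevel=2)
    # shoelace on the closed polygon (V, P)
    area = 0.5 * np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p)
    return float(abs(area))


def _ols(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise FitError("at least two points are required")
    if np.ptp(x) == 0:
        raise FitError("zero spread in the independent variable")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def _select(cycles, during, skip_first):
    if during is None:
        return list(cycles)
    t0, t1 = during
    inside = [c for c in cycles
              if c.time[0] >= t0 - 1e-9 and c.time[-1] <= t1 + 1e-9]
    if skip_first and len(inside) > 2:
        inside = inside[1:]
    return inside


def fit_espvr(cycles, during=None, v_offset: float = 0.0,
              skip_first_in_window: bool = True) -> ESPVRFit:
    """OLS end-systolic pressure-volume relationship over the given beats.

    ``during`` is an optional (t0, t1) window (the occlusion transient);
    the first beat inside it is transitional and skipped by default.
    """
    sel = _select(cycles, during, skip_first_in_window)
    if len(sel) < 2:
        raise FitError("need at least two beats for the ESPVR fit")
    pts = np.array([end_systolic_point(c, v_offset=v_offset) for c in sel])
    slope, intercept, r2 = _ols(pts[:, 0], pts[:, 1])
    if slope == 0:
        raise FitError("degenerate ESPVR fit: zero slope")
    return ESPVRFit(slope=slope, v_intercept=-intercept / slope,
                    n_points=len(sel), r_squared=r2)


def fit_prsw(cycles, during=None, skip_first_in_window: bool = True) -> PRSWFit:
    """OLS stroke work versus end-diastolic volume; the slope is PRSW."""
    sel = _select(cycles, during, skip_first_in_window)
    if len(sel) < 2:
        raise FitError("need at least two beats for the PRSW fit")
    edv = [c.edv for c in sel]
    sw = [stroke_work(c) for c in sel]
    slope, intercept, r2 = _ols(edv, sw)
    return PRSWFit(slope=slope, intercept=intercept,
                   n_points=len(sel), r_squared=r2)


def contractility_sweep(params: ModelParameters, reductions,
                        settings: SolverSettings | None = None):
    """Occlusion run + contractility fits for each systolic-elastance
    reduction; returns a DataFrame (reduction, e_max_isolated, ees, prsw).

    Each run uses the caval-occlusion protocol (20-30 s of a 40 s horizon
    by default) and fits the beats inside the occlusion window, excluding
    the transitional first beat.
    """
    import pandas as pd

    from .activation import max_isolated_elastance
    from .model import assemble_model, simulate
    from .params import reduce_systolic_elastance

    if settings is None:
        settings = SolverSettings(horizon=40.0)
    rows = []
    for red in reductions:
        p = reduce_systolic_elastance(params, red)
        if p.occlusion is None:
            p.occlusion = OcclusionProtocol()
        trace = simulate(assemble_model(p), settings)
        cycles = segment_cycles(trace)
        window = (p.occlusion.t_start, p.occlusion.t_end)
        espvr = fit_espvr(cycles, during=window)
        prsw = fit_prsw(cycles, during=window)
        rows.append({
            "reduction": red,
            "e_max_isolated": max_isolated_elastance(params.left, red),
            "ees": espvr.slope,
            "prsw": prsw.slope,
        })
    return pd.DataFrame(rows, columns=["reduction", "e_max_isolated",
                                       "ees", "prsw"])
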