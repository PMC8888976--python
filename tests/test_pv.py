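"""P-V loop analytics: segmentation, end-systole, stroke work, fits."""

import numpy as np
import pytest

from cardiobcg import DataError, FitError
from cardiobcg.pv import (PVCycle, end_systolic_point, fit_espvr, fit_prsw,
                          segment_cycles, stroke_work)


def _cycle(p, v, t=None):
    p = np.asarray(p, float)
    if t is None:
        t = np.arange(len(p)) * 0.01
    return PVCycle(time=np.asarray(t, float), pressure=p,
                   volume=np.asarray(v, float))


# ---------------------------------------------------------- segmentation
def test_segment_counts_baseline(baseline_trace):
    cycles = segment_cycles(baseline_trace)
    # starts at 5.6, 6.4, ..., 12.8 -> nine complete periods
    assert len(cycles) == 9
    for c in cycles:
        assert c.time[-1] - c.time[0] == pytest.approx(0.799, abs=1e-6)


def test_segment_drops_trailing_partial(baseline_trace):
    t = baseline_trace.time
    keep = t <= 12.9   # truncate mid-cycle
    series = (t[keep], baseline_trace.pressures["left_ventricle"][keep],
              baseline_trace.volumes["left_ventricle"][keep])
    cycles = segment_cycles(series, cycle_starts=baseline_trace.cycle_starts)
    assert cycles[-1].time[-1] < 12.81


def test_segment_file_series_by_volume_maxima():
    from cardiobcg.synth import SyntheticPVConfig, generate_pv_occlusion
    t, p, v, truth = generate_pv_occlusion(SyntheticPVConfig())
    cycles = segment_cycles((t, p, v))      # boundaries from EDV maxima
    # detected boundaries within one sample of the construction period
    assert len(cycles) >= 8
    for c in cycles:
        assert c.time[-1] - c.time[0] == pytest.approx(0.8, abs=2 * 0.004)


def test_segment_requires_full_cycle():
    t = np.arange(50) * 0.01
    with pytest.raises(DataError):
        segment_cycles((t, np.ones(50), np.ones(50)), cycle_starts=[0.0])


# ---------------------------------------------------------- end systole
def test_es_tie_breaks_to_first_sample():
    v = np.arange(100.0, 60.0, -1.0)     # exact ratio ties in floats
    p = 1.5 * v
    ves, pes = end_systolic_point(_cycle(p, v))
    assert ves == pytest.approx(v[0])
    assert pes == pytest.approx(p[0])


def test_es_finds_constructed_maximum():
    v = np.linspace(120, 50, 70)
    p = 80.0 * np.ones(70)
    p[40] = 140.0                    # single constructed ratio maximum
    ves, pes = end_systolic_point(_cycle(p, v))
    assert (ves, pes) == (pytest.approx(v[40]), pytest.approx(140.0))


def test_es_rejects_nonpositive_volume():
    with pytest.raises(DataError):
        end_systolic_point(_cycle(np.ones(20), np.linspace(5, -5, 20)))


def test_es_search_window_excludes_tail():
    v = np.linspace(120, 50, 100)
    p = 80.0 * np.ones(100)
    p[-2] = 500.0                    # artifact in the final 10%
    ves, _ = end_systolic_point(_cycle(p, v))
    assert ves != pytest.approx(v[-2])


# ---------------------------------------------------------- stroke work
def _rectangle(v_lo, v_hi, p_lo, p_hi, per_edge=5):
    """Closed rectangular loop traversed with per_edge samples per side."""
    v = np.concatenate([np.linspace(v_lo, v_hi, per_edge, endpoint=False),
                        np.full(per_edge, v_hi),
                        np.linspace(v_hi, v_lo, per_edge, endpoint=False),
                        np.full(per_edge, v_lo)])
    p = np.concatenate([np.full(per_edge, p_lo),
                        np.linspace(p_lo, p_hi, per_edge, endpoint=False),
                        np.full(per_edge, p_hi),
                        np.linspace(p_hi, p_lo, per_edge, endpoint=False)])
    return _cycle(p, v)


def test_stroke_work_rectangle():
    assert stroke_work(_rectangle(50, 120, 0, 100)) == pytest.approx(7000.0)


def test_stroke_work_degenerate_zero():
    assert stroke_work(_cycle(np.linspace(0, 90, 30),
                              np.full(30, 80.0))) == pytest.approx(0.0)


def test_stroke_work_matches_polygon_oracle():
    """Random star-shaped 50-vertex loops against an independent polygon
    area implementation."""
    from shapely.geometry import Polygon
    rng = np.random.default_rng(7)
    for _ in range(5):
        ang = np.sort(rng.uniform(0, 2 * np.pi, 50))
        rad = rng.uniform(5, 30, 50)
        v = 80 + rad * np.cos(ang)
        p = 60 + rad * np.sin(ang)
        ours = stroke_work(_cycle(p, v))
        oracle = Polygon(zip(v, p)).area
        assert ours == pytest.approx(oracle, rel=1e-9)


def test_stroke_work_invariances():
    rng = np.random.default_rng(11)
    ang = np.sort(rng.uniform(0, 2 * np.pi, 40))
    v = 90 + 25 * np.cos(ang)
    p = 70 + 40 * np.sin(ang)
    base = stroke_work(_cycle(p, v))
    for k in (1, 7, 23):
        rolled = stroke_work(_cycle(np.roll(p, k), np.roll(v, k)))
        assert rolled == pytest.approx(base, rel=1e-12)
    reversed_ = stroke_work(_cycle(p[::-1].copy(), v[::-1].copy()))
    assert reversed_ == pytest.approx(base, rel=1e-12)


def test_stroke_work_warns_on_open_loop():
    c = _rectangle(50, 120, 0, 100)
    v = c.volume[:-8]                   # stop mid-way along a volume ramp
    p = c.pressure[:-8]
    with pytest.warns(UserWarning, match="open P-V loop"):
        stroke_work(_cycle(p, v))


# ------------------------------------------------------------------ fits
def test_espvr_exact_on_collinear_points():
    cycles = []
    for ves, edv in ((40.0, 110.0), (50.0, 120.0), (60.0, 130.0)):
        # down-and-up loop whose interior corner (ves, 2*ves) is the
        # unique pressure/volume ratio maximum
        v = np.concatenate([np.linspace(edv, ves, 16),
                            np.linspace(ves, edv, 15)[1:]])
        p = np.concatenate([np.linspace(10, 2.0 * ves, 16),
                            np.linspace(2.0 * ves, 10, 15)[1:]])
        cycles.append(_cycle(p, v))
    fit = fit_espvr(cycles)
    assert fit.slope == pytest.approx(2.0, rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0)


def test_espvr_needs_two_points():
    with pytest.raises(FitError):
        fit_espvr([_cycle(np.linspace(5, 90, 30), np.linspace(120, 50, 30))])


def test_espvr_zero_volume_spread_is_singular():
    c = _cycle(np.linspace(5, 90, 30), np.linspace(120, 50, 30))
    with pytest.raises(FitError):
        fit_prsw([c, c])


def test_prsw_two_point_slope():
    def loop(edv, sw):
        # rectangle with fixed 50 ml width and height sw/50
        return _rectangle(edv - 50, edv, 5, 5 + sw / 50.0)
    fit = fit_prsw([loop(100, 5000), loop(120, 7000)])
    assert fit.slope == pytest.approx(100.0)


def test_prsw_offset_changes_intercept_not_slope():
    def loops(offset):
        return [_rectangle(edv - 40 + offset, edv + offset, 5, 5 + sw / 40.0)
                for edv, sw in ((100, 5000), (115, 6500), (130, 8000))]
    a = fit_prsw(loops(0.0))
    b = fit_prsw(loops(25.0))
    assert b.slope == pytest.approx(a.slope, rel=1e-9)
    assert b.intercept != pytest.approx(a.intercept)


def test_noise_free_synthetic_recovery_exact():
    from cardiobcg.synth import SyntheticPVConfig, generate_pv_occlusion
    cfg = SyntheticPVConfig()
    t, p, v, truth = generate_pv_occlusion(cfg)
    cycles = segment_cycles((t, p, v), cycle_starts=truth["cycle_starts"])
    espvr = fit_espvr(cycles)
    prsw = fit_prsw(cycles)
    assert espvr.slope == pytest.approx(truth["ees"], rel=1e-6)
    assert espvr.v_intercept == pytest.approx(truth["v0"], abs=1e-6)
    assert prsw.slope == pytest.approx(truth["prsw"], rel=1e-6)


def test_sweep_empty_reductions_gives_empty_table(baseline_params):
    from cardiobcg.pv import contractility_sweep
    table = contractility_sweep(baseline_params, [])
    assert len(table) == 0
    assert list(table.columns) == ["reduction", "e_max_isolated", "ees",
                                   "prsw"]
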