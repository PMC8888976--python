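"""Measurement pipeline: filters, fiducial detection, summaries, statistics."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from cardiobcg import ConfigurationError, DataError
from cardiobcg.signals import (G_CM_S2, SignalRecord, compare_conditions,
                               detect_j_peaks, detect_r_peaks,
                               extract_features, fluctuation_ratio,
                               moods_median_test, preprocess_bcg,
                               preprocess_ecg, summarize)
from cardiobcg.synth import SyntheticSessionConfig, generate_session

FS = 200.0


def _record(ecg=None, acc_z=None, n=2000, mass=30.0):
    ecg = np.zeros(n) if ecg is None else ecg
    acc_z = np.zeros(len(ecg)) if acc_z is None else acc_z
    acc = np.column_stack([np.zeros(len(ecg)), np.zeros(len(ecg)), acc_z])
    return SignalRecord(fs=FS, ecg=ecg, acc=acc, mass_kg=mass)


# ----------------------------------------------------------------- filters
def test_ecg_filter_removes_dc():
    rec = _record(ecg=np.full(4000, 3.7))
    out = preprocess_ecg(rec)
    assert np.abs(out.mean()) < 1e-6 * 3.7


@pytest.mark.parametrize("freq, keep", [(10.0, True), (60.0, False)])
def test_ecg_filter_band(freq, keep):
    t = np.arange(8000) / FS
    rec = _record(ecg=np.sin(2 * np.pi * freq * t))
    out = preprocess_ecg(rec)[2000:-2000]     # ignore edge transients
    amp = np.max(np.abs(out))
    if keep:
        assert amp == pytest.approx(1.0, rel=0.05)
    else:
        assert amp < 10 ** (-20 / 20)          # > 20 dB attenuation


def test_bcg_filter_rejects_low_fs():
    rec = _record()
    rec.fs = 100.0
    with pytest.raises(ConfigurationError):
        preprocess_ecg(rec)


def test_bcg_conversion_sign_and_scale():
    """An in-band 5 Hz acceleration of 1 cm/s^2 on a 30 kg body becomes a
    sign-inverted ~3e4 dyne force."""
    t = np.arange(8000) / FS
    acc_z = (1.0 / G_CM_S2) * np.sin(2 * np.pi * 5.0 * t)    # 1 cm/s^2 in g
    rec = _record(ecg=np.zeros(8000), acc_z=acc_z)
    out = preprocess_bcg(rec)[2000:-2000]
    ref = -30000.0 * np.sin(2 * np.pi * 5.0 * t[2000:-2000])
    amp = np.max(np.abs(out))
    assert amp == pytest.approx(3.0e4, rel=0.05)
    # sign inversion: anticorrelated with the raw acceleration
    assert np.corrcoef(out, -np.sin(2 * np.pi * 5.0 * t[2000:-2000]))[0, 1] < -0.99 or \
           np.corrcoef(out, ref)[0, 1] > 0.99


def test_bcg_scales_linearly_with_mass():
    t = np.arange(4000) / FS
    acc_z = 1e-3 * np.sin(2 * np.pi * 5.0 * t)
    a = preprocess_bcg(_record(ecg=np.zeros(4000), acc_z=acc_z, mass=30.0))
    b = preprocess_bcg(_record(ecg=np.zeros(4000), acc_z=acc_z, mass=60.0))
    assert np.allclose(b, 2.0 * a)


# ----------------------------------------------------------- R detection
def _clean_ecg(bpm=82.0, duration=60.0, invert=False):
    rec, truth = generate_session(SyntheticSessionConfig(
        duration=duration, heart_rate=bpm, rr_jitter_sd=0.0,
        noise_sd=0.0, resp_amplitude=0.0, qs_inversion=invert, seed=1))
    return rec, truth


def test_r_detection_count_and_rate():
    rec, truth = _clean_ecg()
    r = detect_r_peaks(preprocess_ecg(rec), rec.fs)
    assert abs(len(r) - 82) <= 1
    assert np.mean(np.diff(r)) == pytest.approx(60 / 82, abs=1 / FS)


def test_r_detection_invariant_to_inversion():
    rec, _ = _clean_ecg()
    r_up = detect_r_peaks(preprocess_ecg(rec), rec.fs)
    rec.ecg = -rec.ecg                     # QS-inverted morphology
    r_dn = detect_r_peaks(preprocess_ecg(rec), rec.fs)
    assert len(r_up) == len(r_dn)
    assert np.max(np.abs(r_up - r_dn)) <= 1 / FS + 1e-12


def test_r_detection_white_noise_returns_empty():
    rng = np.random.default_rng(5)
    r = detect_r_peaks(rng.normal(0, 1e-3, 4000), FS)
    assert len(r) == 0


def test_r_detection_needs_two_seconds():
    with pytest.raises(DataError):
        detect_r_peaks(np.zeros(100), FS)


# ----------------------------------------------------------- J detection
def test_j_detection_recovers_configured_features():
    rec, truth = generate_session(SyntheticSessionConfig(
        teb=0.110, j_amplitude=4.726e4, seed=3))
    beats, summary = extract_features(rec)
    assert summary.teb_median == pytest.approx(0.110, abs=0.005)
    assert summary.amplitude_median == pytest.approx(4.726e4, rel=0.02)


def test_j_detection_flat_bcg_flags_all_beats():
    rec, _ = _clean_ecg(duration=20.0)
    r = detect_r_peaks(preprocess_ecg(rec), rec.fs)
    beats = detect_j_peaks(np.zeros(len(rec.ecg)), r, rec.fs)
    assert beats and all(not b.accepted for b in beats)
    with pytest.raises(DataError):
        summarize(beats)


def test_j_window_validation():
    with pytest.raises(ConfigurationError):
        detect_j_peaks(np.zeros(1000), [0.5], FS, w_min=0.3, w_max=0.1)
    with pytest.raises(DataError):
        detect_j_peaks(np.zeros(1000), [], FS)


# ------------------------------------------------------------- summaries
def test_summary_median_and_percentile_convention():
    from cardiobcg.signals import BeatFeatures
    beats = [BeatFeatures(r_time=i * 0.7, j_time=i * 0.7 + teb,
                          j_amplitude=1000.0 * (i + 1), accepted=True)
             for i, teb in enumerate([0.10, 0.11, 0.12])]
    s = summarize(beats)
    assert s.teb_median == pytest.approx(0.11)
    # percentile convention on 1..100: linear interpolation
    vals = np.arange(1, 101, dtype=float)
    assert np.percentile(vals, 25) == pytest.approx(25.75)
    beats = [BeatFeatures(r_time=i * 0.5, j_time=i * 0.5 + 0.1,
                          j_amplitude=v, accepted=True) for i, v in
             enumerate(vals)]
    s = summarize(beats)
    assert s.amplitude_p25 == pytest.approx(25.75)
    assert s.amplitude_p75 == pytest.approx(75.25)


def test_summary_heart_rate_from_session():
    rec, _ = generate_session(SyntheticSessionConfig(seed=9))
    _, s = extract_features(rec)
    assert s.heart_rate == pytest.approx(82.0, abs=0.5)


# ------------------------------------------------------------ statistics
def test_moods_identical_samples_not_significant():
    x = np.arange(20.0)
    _, p = moods_median_test(x, x)
    assert p > 0.9


def test_moods_separated_samples_significant():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 1, 20)
    y = rng.uniform(2, 3, 20)
    _, p = moods_median_test(x, y)
    assert p < 0.001


def test_moods_matches_scipy_reference():
    from scipy.stats import median_test as scipy_median_test
    rng = np.random.default_rng(8)
    x = rng.normal(0, 1, 35)
    y = rng.normal(0.6, 1, 41)
    stat, p = moods_median_test(x, y)
    res = scipy_median_test(x, y, ties="below", correction=False)
    assert stat == pytest.approx(res.statistic)
    assert p == pytest.approx(res.pvalue)


def test_moods_close_to_exact_enumeration_on_small_samples():
    """Chi-square approximation within a factor of two of the exact
    (Fisher) tail for small samples."""
    rng = np.random.default_rng(4)
    for _ in range(5):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.8, 1, 9)
        _, p = moods_median_test(x, y)
        grand = np.median(np.concatenate([x, y]))
        table = [[int(np.sum(x > grand)), int(np.sum(y > grand))],
                 [int(np.sum(x <= grand)), int(np.sum(y <= grand))]]
        _, p_exact = fisher_exact(table)
        assert 0.5 <= max(p, 1e-12) / max(p_exact, 1e-12) <= 2.0


def test_moods_degenerate_identical_values():
    with pytest.raises(DataError):
        moods_median_test(np.ones(10), np.ones(12))


# ----------------------------------------------------------- comparisons
def _summary(teb, amp, hr=80.0):
    from cardiobcg.signals import FeatureSummary
    return FeatureSummary(teb_median=teb, teb_p25=teb, teb_p75=teb,
                          amplitude_median=amp, amplitude_p25=amp,
                          amplitude_p75=amp, n_beats=100, heart_rate=hr)


def test_compare_conditions_printed_arithmetic():
    c = compare_conditions(_summary(0.110, 8.364e4),
                           _summary(0.145, 4.726e4))
    assert c.delta_teb == pytest.approx(0.035)
    c2 = compare_conditions(_summary(0.110, 2.430e4),
                            _summary(0.140, 1.872e4))
    assert c2.delta_amplitude == pytest.approx(-0.558e4)


def test_compare_conditions_identical_and_zero_baseline():
    s = _summary(0.1, 1e4)
    c = compare_conditions(s, s)
    assert c.delta_teb == 0.0 and c.percent_amplitude == 0.0
    with pytest.raises(DataError):
        compare_conditions(_summary(0.0, 1e4), s)


def test_fluctuation_ratio_examples():
    assert fluctuation_ratio([0.035, 0.030, 0.035],
                             [0.005, 0.0, 0.0]) == pytest.approx(6.0)
    assert fluctuation_ratio([0.01], [0.01]) == pytest.approx(1.0)
    with pytest.raises(DataError):
        fluctuation_ratio([0.01], [0.0, 0.0])


# ------------------------------------------------------------ invariance
def test_time_shift_equivariance():
    rec, _ = generate_session(SyntheticSessionConfig(duration=60.0, seed=6))
    _, s0 = extract_features(rec)
    k = 37
    shifted = SignalRecord(fs=rec.fs, ecg=np.roll(rec.ecg, k),
                           acc=np.roll(rec.acc, k, axis=0),
                           mass_kg=rec.mass_kg)
    # roll wraps a fraction of a beat across the ends; trim the wrap
    shifted.ecg[:k] = 0.0
    shifted.acc[:k] = 0.0
    _, s1 = extract_features(shifted)
    assert s1.teb_median == pytest.approx(s0.teb_median, abs=1 / rec.fs)


def test_gain_invariance():
    rec, _ = generate_session(SyntheticSessionConfig(duration=60.0, seed=6))
    _, s0 = extract_features(rec)
    rec.acc = rec.acc * 3.0
    _, s3 = extract_features(rec)
    assert s3.teb_median == pytest.approx(s0.teb_median)
    assert s3.amplitude_median == pytest.approx(3.0 * s0.amplitude_median,
                                                rel=1e-9)


def test_pipeline_determinism():
    rec1, _ = generate_session(SyntheticSessionConfig(duration=60.0, seed=12))
    rec2, _ = generate_session(SyntheticSessionConfig(duration=60.0, seed=12))
    b1, s1 = extract_features(rec1)
    b2, s2 = extract_features(rec2)
    assert s1 == s2
    assert all(x == y for x, y in zip(b1, b2))
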