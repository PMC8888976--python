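"""Ground-truth generators for pipeline inputs.

Two families of synthetic data are produced, each with an exact
ground-truth table so estimator error can be measured:

* synchronous ECG + 3-axis accelerometer sessions with a configurable
  heart rate, R-to-J interval (TEB) and J amplitude.  The ECG is a
  per-beat QRS template (optionally inverted to a QS morphology); the
  BCG beat template is a Gaussian-windowed sinusoid whose carrier lies in
  the middle of the 1.25-15 Hz analysis band, so its dominant positive
  peak — placed exactly ``teb`` seconds after each R — survives the
  pipeline's bandpass essentially unchanged.  Respiratory baseline drift
  (outside the passbands) and white noise are added on top.

* caval-occlusion style LV pressure/volume series in which end-diastolic
  volume steps down beat by beat and, by construction, the end-systolic
  points lie exactly on a line of slope Ees and the stroke work is an
  exact linear function of EDV with slope PRSW.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError
from .signals import G_CM_S2, SignalRecord

#: carrier frequency (Hz) of the BCG beat template; mid-band of 1.25-15 Hz
BCG_CARRIER_HZ = 7.0
#: Gaussian envelope width (s) of the BCG beat template
BCG_ENVELOPE_S = 0.08


@dataclass
class SyntheticSessionConfig:
    """Configuration of one synthetic ECG+BCG session."""

    duration: float = 180.0            # s
    fs: float = 200.0                  # samples/s
    heart_rate: float = 82.0           # beats/min
    rr_jitter_sd: float = 0.010        # s, beat-to-beat Gaussian jitter
    teb: float = 0.110                 # s, R-to-J interval
    j_amplitude: float = 8.364e4       # dyne
    noise_sd: float = 2.0e3            # dyne, white noise on the force scale
    resp_amplitude: float = 1.0e4      # dyne, respiratory drift
    resp_freq: float = 0.3             # Hz
    qs_inversion: bool = False
    mass_kg: float = 30.0
    seed: int = 0

    def validate(self) -> "SyntheticSessionConfig":
        rr = 60.0 / self.heart_rate
        if self.teb >= rr:
            raise ConfigurationError(
                f"teb={self.teb}s must be shorter than the beat interval "
                f"{rr:.3f}s")
        if self.fs < 200.0:
            raise ConfigurationError("fs must be at least 200 samples/s")
        if self.duration <= 0 or self.heart_rate <= 0 or self.mass_kg <= 0:
            raise ConfigurationError("duration, heart_rate, mass_kg must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticPVConfig:
    """Configuration of a synthetic occlusion-transient P-V series."""

    ees: float = 1.3                   # mmHg/ml, ground-truth ESPVR slope
    v0: float = -10.0                  # ml, ESPVR volume intercept
    prsw: float = 70.0                 # mmHg, ground-truth SW-EDV slope
    sw_intercept: float = -3500.0      # mmHg*ml
    edv0: float = 140.0                # ml, first-beat EDV
    edv_decrement: float = 8.0         # ml per beat
    n_beats: int = 10
    diastolic_pressure: float = 4.0    # mmHg, loop floor
    period: float = 0.8                # s
    fs: float = 250.0                  # samples/s
    noise_sd_p: float = 0.0            # mmHg
    noise_sd_v: float = 0.0            # ml
    seed: int = 0

    def validate(self) -> "SyntheticPVConfig":
        if self.ees <= 0 or self.prsw <= 0:
            raise ConfigurationError("ees and prsw must be positive")
        if self.edv_decrement <= 0:
            raise ConfigurationError("edv_decrement must be positive")
        if self.n_beats < 2:
            raise ConfigurationError("need at least two beats")
        last_edv = self.edv0 - (self.n_beats - 1) * self.edv_decrement
        if last_edv <= max(self.v0, 0.0):
            raise ConfigurationError("EDV under-runs the volume intercept")
        if self.prsw * last_edv + self.sw_intercept <= 0:
            raise ConfigurationError("configured stroke work becomes "
                                     "non-positive")
        return self


def _qrs_template(fs: float, invert: bool) -> np.ndarray:
    """Narrow R spike with small Q/S side lobes plus a low T bump."""
    t = np.arange(int(0.16 * fs)) / fs - 0.08
    r = 1.2 * np.exp(-0.5 * (t / 0.012) ** 2)
    q = -0.18 * np.exp(-0.5 * ((t + 0.028) / 0.010) ** 2)
    s = -0.25 * np.exp(-0.5 * ((t - 0.030) / 0.012) ** 2)
    qrs = r + q + s
    return -qrs if invert else qrs


def _bcg_template(fs: float, teb: float, amplitude_dyne: float) -> tuple:
    """Gaussian-windowed cosine whose positive peak has the configured
    amplitude; returns (samples, index_of_peak)."""
    half = int(0.30 * fs)
    t = np.arange(-half, half + 1) / fs
    w = amplitude_dyne * np.cos(2 * np.pi * BCG_CARRIER_HZ * t) * \
        np.exp(-0.5 * (t / BCG_ENVELOPE_S) ** 2)
    return w, half


def generate_session(cfg: SyntheticSessionConfig):
    """Synthesize one session.

    Returns (record, truth) where ``truth`` is a dict with the beat table
    (r_times, j_times) and the configured feature values.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    fs = cfg.fs

    rr = 60.0 / cfg.heart_rate
    beat_times = []
    t = 0.3
    while t < cfg.duration - 0.5:
        beat_times.append(t)
        t += rr + rng.normal(0.0, cfg.rr_jitter_sd)
    beat_times = np.asarray(beat_times)

    ecg = np.zeros(n)
    qrs = _qrs_template(fs, cfg.qs_inversion)
    qoff = int(0.08 * fs)          # R apex index within the template
    force = np.zeros(n)
    tmpl, peak = _bcg_template(fs, cfg.teb, cfg.j_amplitude)

    for bt in beat_times:
        i = int(round(bt * fs))
        lo, hi = i - qoff, i - qoff + len(qrs)
        if lo >= 0 and hi <= n:
            ecg[lo:hi] += qrs
        j = int(round((bt + cfg.teb) * fs))
        lo, hi = j - peak, j - peak + len(tmpl)
        if lo >= 0 and hi <= n:
            force[lo:hi] += tmpl

    tt = np.arange(n) / fs
    force = force + cfg.resp_amplitude * np.sin(2 * np.pi * cfg.resp_freq * tt)
    force = force + rng.normal(0.0, cfg.noise_sd, n)
    ecg = ecg + 0.05 * np.sin(2 * np.pi * cfg.resp_freq * tt)
    ecg = ecg + rng.normal(0.0, 0.02, n)

    # the pipeline converts acc_z -> force via (-1) * mass[g] * 980.665;
    # invert that mapping so the configured force amplitudes come back out
    acc_z = -force / (cfg.mass_kg * 1000.0 * G_CM_S2)
    acc = np.column_stack([
        rng.normal(0.0, 2e-4, n),       # x: lateral, noise only
        rng.normal(0.0, 2e-4, n),       # y: head-tail, noise only
        acc_z,
    ])
    rec = SignalRecord(fs=fs, ecg=ecg, acc=acc, mass_kg=cfg.mass_kg,
                       subject="synthetic", session=f"seed{cfg.seed}")
    truth = {
        "r_times": beat_times,
        "j_times": beat_times + cfg.teb,
        "teb": cfg.teb,
        "j_amplitude": cfg.j_amplitude,
        "heart_rate": cfg.heart_rate,
    }
    return rec, truth


def generate_pre_post_pair(base: SyntheticSessionConfig, teb_shift: float,
                           amplitude_factor: float, hr_post: float):
    """A pre/post condition pair: the post session has TEB increased by
    ``teb_shift``, J amplitude scaled by ``amplitude_factor``, heart rate
    ``hr_post`` and a QS-inverted ECG morphology."""
    pre, truth_pre = generate_session(base)
    post_cfg = SyntheticSessionConfig(**{**base.to_dict(), **dict(
        teb=base.teb + teb_shift,
        j_amplitude=base.j_amplitude * amplitude_factor,
        heart_rate=hr_post,
        qs_inversion=True,
        seed=base.seed + 1,
    )})
    post, truth_post = generate_session(post_cfg)
    return (pre, truth_pre), (post, truth_post)


def generate_pv_occlusion(cfg: SyntheticPVConfig):
    """Beat sequence with stepping-down EDV whose contractility indices are
    exact by construction.

    Each beat is a rectangular P-V loop: the end-systolic corner lies on
    P = ees*(V - v0) and the loop area equals prsw*EDV + sw_intercept (the
    stroke volume solving the implied quadratic).  Returns
    (time, pressure, volume, truth).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = int(round(cfg.period * cfg.fs))
    qtr = m // 4
    times, pres, vols = [], [], []
    truth_beats = []
    for b in range(cfg.n_beats):
        edv = cfg.edv0 - b * cfg.edv_decrement
        sw = cfg.prsw * edv + cfg.sw_intercept
        # (ees*(edv - sv - v0) - p_d) * sv = sw  ->  quadratic in sv
        a_ = cfg.ees
        b_ = -(cfg.ees * (edv - cfg.v0) - cfg.diastolic_pressure)
        c_ = sw
        disc = b_ * b_ - 4 * a_ * c_
        if disc <= 0:
            raise ConfigurationError("no real stroke volume for the "
                                     "configured SW line")
        sv = (-b_ - np.sqrt(disc)) / (2 * a_)   # smaller root: physical SV
        esv = edv - sv
        p_es = cfg.ees * (esv - cfg.v0)
        if p_es <= cfg.diastolic_pressure or esv <= 0:
            raise ConfigurationError("non-physical loop from configuration")
        t0 = b * cfg.period
        # four edges: isovolumic rise, ejection, isovolumic fall, filling
        seg_t = np.arange(m) / cfg.fs + t0
        p = np.empty(m)
        v = np.empty(m)
        r1 = np.linspace(cfg.diastolic_pressure, p_es, qtr, endpoint=False)
        p[:qtr] = r1;              v[:qtr] = edv
        v2 = np.linspace(edv, esv, qtr, endpoint=False)
        p[qtr:2 * qtr] = p_es;     v[qtr:2 * qtr] = v2
        r3 = np.linspace(p_es, cfg.diastolic_pressure, qtr, endpoint=False)
        p[2 * qtr:3 * qtr] = r3;   v[2 * qtr:3 * qtr] = esv
        v4 = np.linspace(esv, edv, m - 3 * qtr, endpoint=False)
        p[3 * qtr:] = cfg.diastolic_pressure
        v[3 * qtr:] = v4
        times.append(seg_t); pres.append(p); vols.append(v)
        truth_beats.append({"edv": edv, "esv": esv, "p_es": p_es, "sw": sw})
    time = np.concatenate(times)
    pressure = np.concatenate(pres) + rng.normal(0.0, cfg.noise_sd_p, m * cfg.n_beats)
    volume = np.concatenate(vols) + rng.normal(0.0, cfg.noise_sd_v, m * cfg.n_beats)
    truth = {
        "ees": cfg.ees, "v0": cfg.v0, "prsw": cfg.prsw,
        "sw_intercept": cfg.sw_intercept,
        "cycle_starts": np.arange(cfg.n_beats + 1) * cfg.period,
        "beats": truth_beats,
    }
    return time, pressure, volume, truth
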