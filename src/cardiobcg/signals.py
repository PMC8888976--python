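"""ECG + accelerometer BCG processing into per-beat timing and amplitude
features.

The pipeline mirrors a synchronous two-channel acquisition at 200
samples/s: a 6th-order Butterworth bandpass (0.7-40 Hz) for the ECG and
(1.25-15 Hz) for the accelerometer BCG, both applied forward-backward so
the filter delay cannot bias the timing feature.  The accelerometer
z-axis (floor-to-ceiling) is converted to a force in dyne via Newton's
third law: multiply by -1 (action-reaction) and by the body mass in
grams, with acceleration in cm/s^2.

Per beat, the fiducials are the ECG R peak (detected on the rectified
filtered signal so inverted QS complexes are found at the same instants)
and the BCG J peak (most prominent positive peak in the early systolic
window after R).  TEB is their time difference; sessions are summarized
by medians and quartiles and compared with Mood's median test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.stats import chi2

from .errors import ConfigurationError, DataError

G_CM_S2 = 980.665            # standard gravity, cm/s^2 per g
ECG_BAND_HZ = (0.7, 40.0)
BCG_BAND_HZ = (1.25, 15.0)
FILTER_ORDER = 6             # Butterworth bandpass order
REFRACTORY_S = 0.25          # minimum R-R separation
J_WINDOW_S = (0.05, 0.30)    # J search window after each R peak


@dataclass
class SignalRecord:
    """Synchronous ECG + 3-axis accelerometer session."""

    fs: float                     # samples/s
    ecg: np.ndarray               # mV
    acc: np.ndarray               # (n, 3) in g: x, y, z(floor-to-ceiling)
    mass_kg: float
    sensitivity_mv_per_g: float = 1000.0
    subject: str = ""
    session: str = ""

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise DataError("acc must be an (n, 3) array of x/y/z in g")
        if len(self.ecg) != len(self.acc):
            raise DataError("ecg and acc must have equal length")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.mass_kg is None or self.mass_kg <= 0:
            raise DataError("subject mass (kg) is required and positive")

    @property
    def duration(self) -> float:
        return len(self.ecg) / self.fs


@dataclass
class BeatFeatures:
    """Fiducials and features of one beat."""

    r_time: float                 # s
    j_time: float | None          # s, None when no J accepted
    j_amplitude: float | None     # dyne
    accepted: bool

    @property
    def teb(self) -> float | None:
        """R-to-J interval in seconds (the ECG-BCG timing feature)."""
        if self.j_time is None:
            return None
        return self.j_time - self.r_time


@dataclass
class FeatureSummary:
    """Session-level medians and quartiles."""

    teb_median: float
    teb_p25: float
    teb_p75: float
    amplitude_median: float
    amplitude_p25: float
    amplitude_p75: float
    n_beats: int
    heart_rate: float             # beats/min


def _bandpass_sos(lo, hi, fs):
    # require the upper corner to sit below 0.4*fs so the digital design
    # stays well clear of the Nyquist frequency
    if hi >= 0.4 * fs:
        raise ConfigurationError(
            f"bandpass cutoff {hi} Hz requires fs > {hi / 0.4:g} samples/s, "
            f"got fs={fs}")
    # an order-N Butterworth bandpass has 2N poles; order 6 -> butter N=3
    return sps.butter(FILTER_ORDER // 2, (lo, hi), btype="bandpass",
                      fs=fs, output="sos")


def preprocess_ecg(rec: SignalRecord) -> np.ndarray:
    """Zero-phase 6th-order Butterworth bandpass (0.7-40 Hz) of the ECG."""
    sos = _bandpass_sos(*ECG_BAND_HZ, rec.fs)
    return sps.sosfiltfilt(sos, rec.ecg)


def preprocess_bcg(rec: SignalRecord) -> np.ndarray:
    """Force BCG (dyne) from the accelerometer z-axis.

    g -> cm/s^2, zero-phase 6th-order Butterworth bandpass (1.25-15 Hz),
    polarity flip (action-reaction) and multiplication by the body mass
    in grams.
    """
    acc_z = rec.acc[:, 2] * G_CM_S2
    sos = _bandpass_sos(*BCG_BAND_HZ, rec.fs)
    filtered = sps.sosfiltfilt(sos, acc_z)
    return -filtered * rec.mass_kg * 1000.0


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Beat fiducial times (s) on the rectified filtered ECG.

    A robust adaptive threshold (5 sigma on the MAD scale) with a 250 ms
    refractory period; rectification makes inverted QS complexes yield the
    same fiducials as upright R peaks.  Returns an empty array (with no
    error) when nothing crosses the threshold.
    """
    x = np.abs(np.asarray(ecg, dtype=float))
    if len(x) < 2 * fs:
        raise DataError("R-peak detection requires at least 2 s of signal")
    sigma = 1.4826 * np.median(np.abs(x - np.median(x)))
    # QRS complexes stand tens of robust sigmas above the background, so a
    # high threshold rejects noise without costing sensitivity
    threshold = 8.0 * sigma if sigma > 0 else np.inf
    peaks, _ = sps.find_peaks(x, height=threshold,
                              distance=max(1, int(REFRACTORY_S * fs)))
    return peaks / fs


def detect_j_peaks(fbcg: np.ndarray, r_times, fs: float,
                   w_min: float = J_WINDOW_S[0],
                   w_max: float = J_WINDOW_S[1]) -> list:
    """Per-beat J peak: highest positive local maximum of the force BCG in
    (r + w_min, r + w_max], truncated at the next R.

    Beats with no positive local maximum are flagged (accepted=False).
    """
    if w_min >= w_max:
        raise ConfigurationError("J window requires w_min < w_max")
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size == 0:
        raise DataError("no R peaks supplied")
    fbcg = np.asarray(fbcg, dtype=float)
    n = len(fbcg)
    beats = []
    for b, r in enumerate(r_times):
        hi = r + w_max
        if b + 1 < len(r_times):
            hi = min(hi, r_times[b + 1])
        i0 = int(np.floor((r + w_min) * fs)) + 1
        i1 = min(int(np.floor(hi * fs)), n - 1)
        feat = BeatFeatures(r_time=float(r), j_time=None,
                            j_amplitude=None, accepted=False)
        if i1 > i0 + 1:
            seg = fbcg[i0:i1 + 1]
            local, _ = sps.find_peaks(seg)
            local = local[seg[local] > 0]
            if local.size:
                j = local[np.argmax(seg[local])]
                feat = BeatFeatures(r_time=float(r),
                                    j_time=(i0 + j) / fs,
                                    j_amplitude=float(seg[j]),
                                    accepted=True)
        beats.append(feat)
    return beats


def summarize(features, r_times=None) -> FeatureSummary:
    """Medians and quartiles of TEB and J amplitude over accepted beats;
    heart rate from the mean R-R interval."""
    accepted = [f for f in features if f.accepted]
    if not accepted:
        raise DataError("no accepted beats to summarize")
    teb = np.array([f.teb for f in accepted])
    amp = np.array([f.j_amplitude for f in accepted])
    if r_times is None:
        r_times = np.array([f.r_time for f in features])
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) < 2:
        raise DataError("heart rate needs at least two R peaks")
    hr = 60.0 / float(np.mean(np.diff(r_times)))
    q = lambda a, p: float(np.percentile(a, p))  # linear interpolation
    return FeatureSummary(
        teb_median=q(teb, 50), teb_p25=q(teb, 25), teb_p75=q(teb, 75),
        amplitude_median=q(amp, 50), amplitude_p25=q(amp, 25),
        amplitude_p75=q(amp, 75), n_beats=len(accepted), heart_rate=hr)


def extract_features(rec: SignalRecord):
    """Full per-session pipeline: filter, detect, summarize.

    Returns (beats, summary).
    """
    ecg_f = preprocess_ecg(rec)
    fbcg = preprocess_bcg(rec)
    r_times = detect_r_peaks(ecg_f, rec.fs)
    if r_times.size == 0:
        raise DataError("no R peaks detected")
    beats = detect_j_peaks(fbcg, r_times, rec.fs)
    return beats, summarize(beats, r_times)


def moods_median_test(x, y, correction: bool = False):
    """Mood's median test: 2x2 classification against the grand median
    followed by a chi-square test with 1 degree of freedom.

    Values equal to the grand median count in the "<=" cell; Yates
    continuity correction is off by default.  Returns (statistic, p_value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    grand = np.median(np.concatenate([x, y]))
    table = np.array([[np.sum(x > grand), np.sum(y > grand)],
                      [np.sum(x <= grand), np.sum(y <= grand)]], dtype=float)
    if np.any(table.sum(axis=1) == 0):
        raise DataError("degenerate table: all values on one side of the "
                        "grand median")
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / n
    diff = np.abs(table - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff ** 2 / expected))
    p = float(chi2.sf(stat, df=1))
    return stat, p


@dataclass
class ConditionComparison:
    """Differences between two session summaries (b minus a)."""

    delta_teb: float                    # s
    delta_amplitude: float              # dyne
    percent_teb: float
    percent_amplitude: float
    extras: dict = field(default_factory=dict)


def compare_conditions(a: FeatureSummary, b: FeatureSummary,
                       **paired_scalars) -> ConditionComparison:
    """Median differences and percent changes between two conditions.

    Additional paired scalars can be passed as ``name=(value_a, value_b)``;
    their absolute and percent changes are reported under ``extras``.
    """
    def pct(va, vb):
        if va == 0:
            raise DataError("percent change undefined for a zero baseline")
        return (vb - va) / va * 100.0

    extras = {}
    for name, (va, vb) in paired_scalars.items():
        extras[name] = {"delta": vb - va, "percent": pct(va, vb)}
    return ConditionComparison(
        delta_teb=b.teb_median - a.teb_median,
        delta_amplitude=b.amplitude_median - a.amplitude_median,
        percent_teb=pct(a.teb_median, b.teb_median),
        percent_amplitude=pct(a.amplitude_median, b.amplitude_median),
        extras=extras)


def fluctuation_ratio(mi_deltas, session_deltas) -> float:
    """Ratio of the smallest condition-change magnitude to the largest
    session-to-session fluctuation magnitude.

    Used to ask whether a pathological change stands clear of natural
    variability: a ratio of r means the smallest disease effect is r times
    the largest repeat-session fluctuation.
    """
    mi = np.abs(np.asarray(mi_deltas, dtype=float))
    ses = np.abs(np.asarray(session_deltas, dtype=float))
    if mi.size == 0 or ses.size == 0:
        raise DataError("both delta lists must be non-empty")
    if np.max(ses) == 0:
        raise DataError("zero session variation: ratio undefined")
    return float(np.min(mi) / np.max(ses))
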