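"""File formats: delimited-text readers/writers and structured reports.

All on-disk formats are plain text: UTF-8, comma-separated, '.' decimal,
mandatory header row.  Signal files carry columns
``time_s, ecg_mV, acc_x_g, acc_y_g, acc_z_g`` with a JSON metadata sidecar
(``mass_kg``, ``sensitivity_mV_per_g``, ``fs`` and labels); solution traces
name every column with compartment, quantity and unit.  Reports are JSON
and embed the package version, a config hash and the seed used.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .model import SolutionTrace
from .signals import BeatFeatures, FeatureSummary, SignalRecord

SIGNAL_COLUMNS = ("time_s", "ecg_mV", "acc_x_g", "acc_y_g", "acc_z_g")


def write_signal_file(rec: SignalRecord, path, meta_path=None) -> None:
    """Write a session to CSV + JSON sidecar (``<path>.meta.json`` default)."""
    path = Path(path)
    t = np.arange(len(rec.ecg)) / rec.fs
    df = pd.DataFrame({
        "time_s": t, "ecg_mV": rec.ecg,
        "acc_x_g": rec.acc[:, 0], "acc_y_g": rec.acc[:, 1],
        "acc_z_g": rec.acc[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.8g")
    meta = {
        "fs": rec.fs, "mass_kg": rec.mass_kg,
        "sensitivity_mV_per_g": rec.sensitivity_mv_per_g,
        "subject": rec.subject, "session": rec.session,
    }
    meta_path = Path(meta_path) if meta_path else path.with_suffix(
        path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")


def read_signal_file(path, meta_path=None) -> SignalRecord:
    """Read a session CSV + metadata sidecar into a :class:`SignalRecord`.

    Raises :class:`DataError` naming a missing column, on non-uniform
    sampling (>1% deviation of any interval) or on missing mass.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in SIGNAL_COLUMNS:
        if col not in df.columns:
            raise DataError(f"signal file {path.name} lacks column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 3:
        raise DataError("signal file too short")
    dt = np.diff(t)
    if np.any(np.abs(dt - np.median(dt)) > 0.01 * np.median(dt)):
        raise DataError("non-uniform sampling: time steps deviate by more "
                        "than 1%")
    meta_path = Path(meta_path) if meta_path else path.with_suffix(
        path.suffix + ".meta.json")
    if not meta_path.exists():
        raise DataError(f"metadata sidecar {meta_path.name} not found")
    meta = json.loads(meta_path.read_text())
    if "mass_kg" not in meta or meta["mass_kg"] is None:
        raise DataError("metadata lacks mass_kg")
    fs = float(meta.get("fs") or 1.0 / np.median(dt))
    acc = df[["acc_x_g", "acc_y_g", "acc_z_g"]].to_numpy(dtype=float)
    return SignalRecord(
        fs=fs, ecg=df["ecg_mV"].to_numpy(dtype=float), acc=acc,
        mass_kg=float(meta["mass_kg"]),
        sensitivity_mv_per_g=float(meta.get("sensitivity_mV_per_g", 1000.0)),
        subject=str(meta.get("subject", "")),
        session=str(meta.get("session", "")))


def write_trace(trace: SolutionTrace, path) -> None:
    """Solution trace as CSV with unit-bearing column names."""
    trace.to_frame().to_csv(Path(path), index=False, float_format="%.10g")


def read_pv_file(path):
    """Delimited LV catheter-style series: columns time, P_mmHg, V_ml
    (header names matched loosely).  Returns (time, pressure, volume)."""
    df = pd.read_csv(Path(path))
    cols = {c.lower().split("_")[0]: c for c in df.columns}
    missing = [k for k in ("time", "p", "v") if k not in cols]
    if missing:
        raise DataError(f"P-V file lacks columns for {missing}")
    return (df[cols["time"]].to_numpy(float),
            df[cols["p"]].to_numpy(float),
            df[cols["v"]].to_numpy(float))


def write_beat_table(beats, path) -> None:
    rows = [{
        "r_time_s": b.r_time,
        "j_time_s": b.j_time if b.j_time is not None else np.nan,
        "teb_s": b.teb if b.teb is not None else np.nan,
        "j_amplitude_dyne": (b.j_amplitude if b.j_amplitude is not None
                             else np.nan),
        "accepted": b.accepted,
    } for b in beats]
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format="%.8g")


def summary_dict(s: FeatureSummary) -> dict:
    return {
        "teb_s": {"median": s.teb_median, "p25": s.teb_p25, "p75": s.teb_p75},
        "amplitude_dyne": {"median": s.amplitude_median,
                           "p25": s.amplitude_p25, "p75": s.amplitude_p75},
        "n_beats": s.n_beats,
        "heart_rate_bpm": s.heart_rate,
    }


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(payload: dict, path, config=None, seed=None) -> None:
    """JSON report stamped with package version, config hash and seed."""
    from . import __version__
    out = {
        "package_version": __version__,
        "config_hash": config_hash(config if config is not None else payload),
        "seed": seed,
    }
    out.update(payload)
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
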