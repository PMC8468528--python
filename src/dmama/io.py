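"""Plain-text session I/O: CSV streams and JSON geometry sidecars.

Formats are deliberately inspectable: a session is a CSV of time-stamped
wrench samples (``time_s, fx_n, fy_n, fz_n, mx_nm, my_nm, mz_nm``), labels
and stride tables are CSV, and geometry is a JSON sidecar with the
row-major rotation matrix, joint-to-sensor offsets in metres, foot length
and body weight.  Every file written carries the generating seed and a
config hash in a comment header (CSV) or ``_meta`` field (JSON) for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .series import LOAD_CELL_FRAME, SubjectGeometry, WrenchSeries

SESSION_COLUMNS = ["time_s", "fx_n", "fy_n", "fz_n", "mx_nm", "my_nm", "mz_nm"]
STRIDE_COLUMNS = ["stride_id", "hs_time_s", "to_time_s", "mode", "stiffness_code", "excluded"]
CALIBRATION_COLUMNS = (
    [f"r{i}{j}" for i in range(1, 4) for j in range(1, 4)]
    + ["ankle_x_m", "ankle_y_m", "ankle_z_m", "knee_x_m", "knee_y_m", "knee_z_m"]
)


def config_hash(config) -> str:
    """Short stable hash of a configuration object for provenance headers."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = {k: repr(v) for k, v in sorted(dataclasses.asdict(config).items())}
    else:
        payload = {k: repr(v) for k, v in sorted(dict(config).items())}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _meta_header(seed, cfg_hash) -> str:
    return f"# seed={seed} config_sha={cfg_hash}\n"


def write_csv(path, frame: pd.DataFrame, seed=None, cfg_hash=None, float_format=None):
    # default float_format=None keeps pandas' shortest round-trip repr, so
    # written values read back bit-identical
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(_meta_header(seed, cfg_hash or "-"))
        frame.to_csv(fh, index=False, float_format=float_format)


def write_session_csv(path, series: WrenchSeries, seed=None, cfg_hash=None):
    frame = pd.DataFrame(
        np.column_stack([series.time, series.force, series.moment]),
        columns=SESSION_COLUMNS,
    )
    write_csv(path, frame, seed=seed, cfg_hash=cfg_hash)


def read_session_csv(path, frame: str = LOAD_CELL_FRAME) -> WrenchSeries:
    """Read a wrench stream, validating as it goes.

    Malformed or non-numeric rows and backwards timestamps are rejected
    with 1-based data-row numbers in the error message; an empty file is
    an error, not an empty series.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty session file") from None
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: session file has no data rows")
    values = df[SESSION_COLUMNS].apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if len(bad):
        raise ValueError(f"{path}: malformed value in data row {bad[0] + 1}")
    t = values[:, 0]
    nonmono = np.flatnonzero(np.diff(t) <= 0)
    if len(nonmono):
        raise ValueError(
            f"{path}: non-monotonic timestamp at data row {nonmono[0] + 2}"
        )
    return WrenchSeries(time=t, force=values[:, 1:4], moment=values[:, 4:7], frame=frame)


def write_geometry_json(path, geometry: SubjectGeometry, seed=None, cfg_hash=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "rotation_lc_to_shank": geometry.rotation_lc_to_shank.reshape(-1).tolist(),
        "r_ankle_to_lc_m": geometry.r_ankle_to_lc.tolist(),
        "r_knee_to_lc_m": geometry.r_knee_to_lc.tolist(),
        "foot_length_m": geometry.foot_length,
        "body_weight_n": geometry.body_weight,
    }
    if seed is not None:
        doc["_meta"] = {"seed": seed, "config_sha": cfg_hash or "-"}
    path.write_text(json.dumps(doc, indent=2) + "\n")


def read_geometry_json(path) -> SubjectGeometry:
    path = Path(path)
    doc = json.loads(path.read_text())
    required = [
        "rotation_lc_to_shank",
        "r_ankle_to_lc_m",
        "r_knee_to_lc_m",
        "foot_length_m",
        "body_weight_n",
    ]
    missing = [k for k in required if k not in doc]
    if missing:
        raise ValueError(f"{path}: geometry file missing fields {missing}")
    return SubjectGeometry(
        rotation_lc_to_shank=np.asarray(doc["rotation_lc_to_shank"], float).reshape(3, 3),
        r_ankle_to_lc=np.asarray(doc["r_ankle_to_lc_m"], float),
        r_knee_to_lc=np.asarray(doc["r_knee_to_lc_m"], float),
        foot_length=float(doc["foot_length_m"]),
        body_weight=float(doc["body_weight_n"]),
    )


def read_labels_csv(path) -> pd.DataFrame:
    """Per-sample annotation: time_s, mode, stiffness_code, transition_flag."""
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty labels file") from None
    required = {"time_s", "mode", "stiffness_code", "transition_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: labels file missing columns {sorted(missing)}")
    df["transition_flag"] = df["transition_flag"].astype(bool)
    return df


def read_strides_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty strides file") from None
    missing = [c for c in STRIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: strides file missing columns {missing}")
    return df


def write_calibration_csv(path, rotations, ankle_offsets, knee_offsets, seed=None, cfg_hash=None):
    """Calibration samples: 9 row-major rotation entries + 6 offset components per row."""
    rot = np.asarray(rotations).reshape(len(rotations), 9)
    frame = pd.DataFrame(
        np.column_stack([rot, ankle_offsets, knee_offsets]), columns=CALIBRATION_COLUMNS
    )
    write_csv(path, frame, seed=seed, cfg_hash=cfg_hash)


def read_calibration_csv(path):
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty calibration file") from None
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: calibration file missing columns {missing}")
    arr = df[CALIBRATION_COLUMNS].to_numpy(float)
    return arr[:, :9].reshape(-1, 3, 3), arr[:, 9:12], arr[:, 12:15]


def write_json(path, doc: dict):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(doc, indent=2, default=default, allow_nan=True) + "\n")
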