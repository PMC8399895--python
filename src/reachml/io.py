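"""Recording CSVs and cohort manifests.

One trial per CSV file: comment lines (``#``) carry trial metadata, then a
header row ``time_s`` followed by ``<sensor>_{x,y,z,a,b,g}`` for each of the
four sensors, full float precision ('.' decimal separator, comma delimiter,
UTF-8). The manifest is a delimited table with one row per trial.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .simulate import CONDITIONS, SENSORS, TARGET_SEQUENCE, TrajectoryRecording

_AXES = ("x", "y", "z")
_ANGLE_AXES = ("a", "b", "g")

#: Expected data columns, in file order.
COLUMNS: Tuple[str, ...] = ("time_s",) + tuple(
    f"{sensor}_{axis}"
    for sensor in SENSORS
    for axis in _AXES + _ANGLE_AXES
)

_META_FIELDS = ("subject_id", "arm", "target_label", "condition", "fs",
                "true_onset_idx", "true_offset_idx")

MANIFEST_COLUMNS = (
    "subject_id", "condition", "handedness", "arm", "target", "cycle",
    "file", "true_onset_idx", "true_offset_idx",
)


def write_recording(recording: TrajectoryRecording, path: str,
                    overwrite: bool = False) -> str:
    """Write one trial to CSV; refuses to clobber unless ``overwrite``.

    Only stream consistency (equal lengths, all four sensors) is enforced
    here, so minimal hand-built recordings can be persisted; use
    ``recording.validate()`` for the full physical contract.
    """
    n = recording.n_samples
    for sensor in SENSORS:
        if recording.positions[sensor].shape != (n, 3) or recording.angles[
            sensor
        ].shape != (n, 3):
            raise ValueError(f"stream shape mismatch for sensor {sensor!r}")
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    data = {"time_s": recording.timestamps}
    for sensor in SENSORS:
        for j, axis in enumerate(_AXES):
            data[f"{sensor}_{axis}"] = recording.positions[sensor][:, j]
        for j, axis in enumerate(_ANGLE_AXES):
            data[f"{sensor}_{axis}"] = recording.angles[sensor][:, j]
    frame = pd.DataFrame(data, columns=list(COLUMNS))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for field in _META_FIELDS:
            value = getattr(recording, field)
            if value is not None:
                fh.write(f"# {field}={value}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")
    return path


def _parse_metadata(path: str) -> Dict[str, str]:
    meta: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_recording(path: str) -> TrajectoryRecording:
    """Read one trial CSV back into a :class:`TrajectoryRecording`.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`DataError` for empty files or non-monotone timestamps.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    meta = _parse_metadata(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: file is empty") from exc
    if frame.empty:
        raise DataError(f"{path}: no data rows")
    for column in COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"{path}: missing required column {column!r}")

    timestamps = frame["time_s"].to_numpy(dtype=float)
    if timestamps.size >= 2 and np.any(np.diff(timestamps) <= 0):
        raise DataError(f"{path}: timestamps are not strictly increasing")

    positions = {}
    angles = {}
    for sensor in SENSORS:
        positions[sensor] = frame[
            [f"{sensor}_{axis}" for axis in _AXES]
        ].to_numpy(dtype=float)
        angles[sensor] = frame[
            [f"{sensor}_{axis}" for axis in _ANGLE_AXES]
        ].to_numpy(dtype=float)

    fs = float(meta.get("fs", np.round(1.0 / np.median(np.diff(timestamps)), 6)
                        if timestamps.size >= 2 else 30.0))

    def _idx(key: str) -> Optional[int]:
        return int(meta[key]) if key in meta else None

    rec = TrajectoryRecording(
        subject_id=meta.get("subject_id", ""),
        arm=meta.get("arm", ""),
        target_label=meta.get("target_label", ""),
        condition=meta.get("condition", ""),
        fs=fs,
        timestamps=timestamps,
        positions=positions,
        angles=angles,
        true_onset_idx=_idx("true_onset_idx"),
        true_offset_idx=_idx("true_offset_idx"),
    )
    return rec


def validate_manifest(manifest: pd.DataFrame) -> None:
    """Check manifest invariants; raise :class:`DataError` on violation."""
    for column in MANIFEST_COLUMNS:
        if column not in manifest.columns:
            raise SchemaError(f"manifest missing column {column!r}")
    files = manifest["file"].astype(str)
    nonempty = files[files != ""]
    if nonempty.duplicated().any():
        raise DataError("manifest file paths are not unique")
    bad_cond = set(manifest["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise DataError(f"unknown conditions in manifest: {sorted(bad_cond)}")
    bad_target = set(manifest["target"]) - set(TARGET_SEQUENCE)
    if bad_target:
        raise DataError(f"unknown targets in manifest: {sorted(bad_target)}")


def write_manifest(manifest: pd.DataFrame, path: str) -> str:
    validate_manifest(manifest)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path: str) -> pd.DataFrame:
    try:
        manifest = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: manifest is empty") from exc
    validate_manifest(manifest)
    return manifest


def write_cohort(
    recordings: List[TrajectoryRecording],
    manifest: pd.DataFrame,
    out_dir: str,
    overwrite: bool = False,
) -> str:
    """Write every recording plus the manifest under ``out_dir``.

    Returns the manifest path. File names encode subject, arm, cycle and
    target so the directory is self-describing.
    """
    if len(recordings) != len(manifest):
        raise ValueError("manifest length does not match number of recordings")
    os.makedirs(out_dir, exist_ok=True)
    manifest = manifest.copy()
    counters: Dict[str, int] = {}
    paths = []
    for rec in recordings:
        key = f"{rec.subject_id}_{rec.arm}_{rec.target_label}"
        counters[key] = counters.get(key, 0) + 1
        name = f"{key}_c{counters[key]}.csv"
        write_recording(rec, os.path.join(out_dir, name), overwrite=overwrite)
        paths.append(name)
    manifest["file"] = paths
    return write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))


def read_cohort(manifest_path: str) -> Tuple[List[TrajectoryRecording], pd.DataFrame]:
    """Load all recordings referenced by a manifest (paths relative to it)."""
    manifest = read_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    recordings = [
        read_recording(os.path.join(base, str(row.file)))
        for row in manifest.itertuples()
    ]
    return recordings, manifest
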