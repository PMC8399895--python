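"""Observation windows, min/max/RMS feature extraction, and rescaling.

Only the earliest portion of each movement — the observation window (OW),
anchored at the detected motion onset — feeds the classifiers, because the
goal is predicting where a movement is heading before it completes. Two
sizing strategies exist: a *custom* window proportional to the trial's own
motion duration, and an *average* window fixed from the dataset-mean
duration. Features are the minimum, maximum and root-mean-square of selected
source signals (position modulus SP, speed SV, acceleration modulus SA,
Euler angles SEA) on the hand and arm sensors only; the shoulder and trunk
sensors carry negligible class information by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinematics import lowpass_zero_phase, modulus, two_point_derivative
from .kinematics import SegmentationResult
from .simulate import TrajectoryRecording

#: Source-signal identifiers.
SOURCE_SIGNALS: Tuple[str, ...] = ("SP", "SV", "SA", "SEA")
#: Sensors whose data feed the feature set.
FEATURE_SENSORS: Tuple[str, ...] = ("hand", "arm")
_STATS: Tuple[str, ...] = ("min", "max", "rms")

#: Channel names contributed by each source signal.
_SOURCE_CHANNELS: Dict[str, Tuple[str, ...]] = {
    "SP": ("pos",),
    "SV": ("vel",),
    "SA": ("acc",),
    "SEA": ("ea_a", "ea_b", "ea_g"),
}

#: Rescaling target range for training features.
RESCALE_LIMIT = 0.80

#: Label columns appended to feature tables.
LABEL_COLUMNS: Tuple[str, ...] = ("target", "arm", "condition", "subject_id")


@dataclass(frozen=True)
class ObservationWindowSpec:
    """Resolved observation window: strategy, fraction and sample count."""

    strategy: str
    fraction: Fraction
    resolved_samples: int

    def __post_init__(self) -> None:
        if self.strategy not in ("custom", "average"):
            raise ValueError("strategy must be 'custom' or 'average'")
        if self.resolved_samples < 2:
            raise ValueError("resolved_samples must be >= 2")


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values plus the trial's task labels."""

    names: Tuple[str, ...]
    values: np.ndarray
    target: str
    arm: str
    condition: str
    subject_id: str

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names/values length mismatch")


def average_window_samples(
    durations: Sequence[float], fraction: float, fs: float
) -> int:
    """Fixed OW size from the dataset-mean motion duration.

    ``floor(mean(durations) * fraction * fs)``, clamped to at least 2.
    """
    durations = np.asarray(list(durations), dtype=float)
    if durations.size == 0:
        raise ValueError("at least one motion duration is required")
    if np.any(durations <= 0):
        raise ValueError("all durations must be positive")
    return max(_floor_samples(durations.mean() * fs * float(fraction)), 2)


def custom_window_samples(duration: float, fraction: float, fs: float) -> int:
    """Per-trial OW size: ``floor(duration * fraction * fs)``, min 2."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return max(_floor_samples(duration * fs * float(fraction)), 2)


def _floor_samples(x: float) -> int:
    # Guard against float round-off pushing an exact product (e.g. 63/7)
    # just below the integer before flooring.
    return int(np.floor(x + 1e-9))


def compute_channels(
    recording: TrajectoryRecording,
    source_signals: Iterable[str] = SOURCE_SIGNALS,
    fc: float = 3.0,
    order: int = 4,
) -> Dict[str, np.ndarray]:
    """Full-length channel series for the hand and arm sensors.

    pos — raw position modulus; vel — |low-passed derivative of the
    low-passed modulus|; acc — |low-passed second derivative| (a fictitious
    accelerometer); ea_a/ea_b/ea_g — raw Euler angles. Keys are
    ``f"{sensor}_{channel}"``.
    """
    sources = _check_sources(source_signals)
    channels: Dict[str, np.ndarray] = {}
    fs = recording.fs
    for sensor in FEATURE_SENSORS:
        pos_mod = modulus(recording.positions[sensor])
        if {"SV", "SA"} & sources:
            pos_f = lowpass_zero_phase(pos_mod, fs, fc, order)
            vel = lowpass_zero_phase(two_point_derivative(pos_f, fs), fs, fc, order)
        if "SP" in sources:
            channels[f"{sensor}_pos"] = pos_mod
        if "SV" in sources:
            channels[f"{sensor}_vel"] = np.abs(vel)
        if "SA" in sources:
            acc = lowpass_zero_phase(two_point_derivative(vel, fs), fs, fc, order)
            channels[f"{sensor}_acc"] = np.abs(acc)
        if "SEA" in sources:
            for j, axis in enumerate(("ea_a", "ea_b", "ea_g")):
                channels[f"{sensor}_{axis}"] = recording.angles[sensor][:, j]
    return channels


def _check_sources(source_signals: Iterable[str]) -> set:
    sources = set(source_signals)
    if not sources:
        raise ValueError("source-signal set must be non-empty")
    unknown = sources - set(SOURCE_SIGNALS)
    if unknown:
        raise ValueError(f"unknown source signals: {sorted(unknown)}")
    return sources


def feature_names(source_signals: Iterable[str]) -> Tuple[str, ...]:
    """Canonical feature-name grid: sensor x channel x statistic."""
    sources = _check_sources(source_signals)
    names = []
    for sensor in FEATURE_SENSORS:
        for source in SOURCE_SIGNALS:          # canonical order
            if source not in sources:
                continue
            for channel in _SOURCE_CHANNELS[source]:
                for stat in _STATS:
                    names.append(f"{sensor}_{channel}_{stat}")
    return tuple(names)


def _window_stats(series: np.ndarray) -> Tuple[float, float, float]:
    return (
        float(series.min()),
        float(series.max()),
        float(np.sqrt(np.mean(series**2))),
    )


def features_from_channels(
    channels: Dict[str, np.ndarray],
    recording: TrajectoryRecording,
    segmentation: SegmentationResult,
    ow_samples: int,
    source_signals: Iterable[str],
) -> FeatureVector:
    """Slice precomputed channels on the OW and take min/max/RMS."""
    sources = _check_sources(source_signals)
    motion_len = segmentation.end_idx - segmentation.start_idx + 1
    if ow_samples > motion_len:
        raise ValueError(
            f"window of {ow_samples} samples exceeds the {motion_len}-sample "
            "motion segment"
        )
    if ow_samples < 2:
        raise ValueError("ow_samples must be >= 2")
    lo = segmentation.start_idx
    hi = lo + ow_samples
    names = feature_names(sources)
    values = np.empty(len(names))
    i = 0
    for sensor in FEATURE_SENSORS:
        for source in SOURCE_SIGNALS:
            if source not in sources:
                continue
            for channel in _SOURCE_CHANNELS[source]:
                stats = _window_stats(channels[f"{sensor}_{channel}"][lo:hi])
                values[i : i + 3] = stats
                i += 3
    return FeatureVector(
        names=names,
        values=values,
        target=recording.target_label,
        arm=recording.arm,
        condition=recording.condition,
        subject_id=recording.subject_id,
    )


def extract_features(
    recording: TrajectoryRecording,
    segmentation: SegmentationResult,
    ow_samples: int,
    source_signals: Iterable[str],
    fc: float = 3.0,
    order: int = 4,
) -> FeatureVector:
    """Min/max/RMS features over the observation window.

    The window spans ``[start_idx, start_idx + ow_samples)`` of the detected
    motion; hand and arm sensors contribute one channel per scalar source
    signal (position modulus, speed, acceleration modulus) and three for the
    Euler angles. Raises ``ValueError`` if the window exceeds the motion
    segment.
    """
    channels = compute_channels(recording, source_signals, fc, order)
    return features_from_channels(
        channels, recording, segmentation, ow_samples, source_signals
    )


def feature_table(feature_vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a table with trailing label columns."""
    if len(feature_vectors) == 0:
        raise ValueError("no feature vectors supplied")
    names = feature_vectors[0].names
    for fv in feature_vectors:
        if fv.names != names:
            raise ValueError("feature vectors have inconsistent names")
    frame = pd.DataFrame(
        np.vstack([fv.values for fv in feature_vectors]), columns=list(names)
    )
    frame["target"] = [fv.target for fv in feature_vectors]
    frame["arm"] = [fv.arm for fv in feature_vectors]
    frame["condition"] = [fv.condition for fv in feature_vectors]
    frame["subject_id"] = [fv.subject_id for fv in feature_vectors]
    return frame


class FeatureRescaler:
    """Per-feature affine map sending train min/max to -0.80/+0.80.

    Fitted on the training split only and applied unchanged elsewhere, so
    test values may exceed the +/-0.80 band. A feature constant on the
    training data maps to zero everywhere.
    """

    def __init__(self) -> None:
        self.names_: Tuple[str, ...] = ()
        self.scale_: np.ndarray = np.empty(0)
        self.offset_: np.ndarray = np.empty(0)

    def fit(self, train: pd.DataFrame) -> "FeatureRescaler":
        if train.shape[0] == 0:
            raise ValueError("training matrix is empty")
        self.names_ = tuple(train.columns)
        values = train.to_numpy(dtype=float)
        lo = values.min(axis=0)
        hi = values.max(axis=0)
        span = hi - lo
        constant = span == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            self.scale_ = np.where(constant, 0.0, 2 * RESCALE_LIMIT / span)
        self.offset_ = np.where(constant, 0.0, -RESCALE_LIMIT - self.scale_ * lo)
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if tuple(matrix.columns) != self.names_:
            raise ValueError("feature-name mismatch between matrices")
        values = matrix.to_numpy(dtype=float) * self.scale_ + self.offset_
        return pd.DataFrame(values, columns=list(self.names_), index=matrix.index)


def rescale_features(
    train: pd.DataFrame, *others: pd.DataFrame
) -> Tuple[pd.DataFrame, ...]:
    """Rescale the training matrix to [-0.80, +0.80] per feature and apply
    the same affine maps to any further matrices. Returns the rescaled
    matrices followed by the fitted :class:`FeatureRescaler`."""
    rescaler = FeatureRescaler().fit(train)
    out = [rescaler.transform(train)]
    out.extend(rescaler.transform(other) for other in others)
    out.append(rescaler)
    return tuple(out)
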