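"""Test registries (IP1-IP20, HD1-HD8) and pipeline orchestration.

Each registry entry fixes one evaluation protocol: observation-window
strategy and fraction, source-signal set, whether the left/right arm is an
additional output, the task, and the training fraction (85% for intention
prediction, 90% for health-condition detection). ``run_test`` executes the
full chain — segmentation, anthropometric normalization, window resolution,
feature extraction, train-only rescaling, repeated stratified evaluation —
for one entry; ``run_matrix`` sweeps many entries and tabulates the results.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .classify import (
    ALGORITHMS,
    DEFAULT_TREES_HD,
    DEFAULT_TREES_IP,
    EvaluationResult,
    LabelScheme,
    repeated_evaluation,
)
from .errors import ConfigurationError
from .features import (
    ObservationWindowSpec,
    average_window_samples,
    compute_channels,
    custom_window_samples,
    feature_table,
    features_from_channels,
)
from .kinematics import (
    SegmentationParams,
    SegmentationResult,
    anthropometric_reference,
    hand_speed,
    normalize_recording,
    segment_motion,
)
from .simulate import CONDITIONS, TrajectoryRecording

POPULATIONS: Tuple[str, ...] = ("all", "healthy", "pathological")

ONE_SEVENTH = Fraction(1, 7)
ONE_TENTH = Fraction(1, 10)


@dataclass(frozen=True)
class TestConfig:
    """One registry row: protocol knobs for a single test."""

    test_id: str
    task: str                       # 'IP' or 'HD'
    ow_strategy: str                # 'custom' or 'average'
    fraction: Fraction
    source_signals: Tuple[str, ...]
    lr_distinction: bool
    train_fraction: float

    @property
    def n_trees(self) -> int:
        return DEFAULT_TREES_IP if self.task == "IP" else DEFAULT_TREES_HD

    @property
    def label_scheme(self) -> LabelScheme:
        return LabelScheme(task=self.task, lr_distinction=self.lr_distinction)


def _build_registry() -> Dict[str, TestConfig]:
    registry: Dict[str, TestConfig] = {}
    # Intention prediction: IP1-IP10 custom window, IP11-IP20 average window;
    # within each decade rows 1-5 use a 1/10 window and rows 6-10 a 1/7
    # window, cycling the source sets (SP+SV, SP+SV+SEA, SP, SA, SA) with the
    # arm distinction on except for the final SA row.
    signal_cycle = [
        (("SP", "SV"), True),
        (("SP", "SV", "SEA"), True),
        (("SP",), True),
        (("SA",), True),
        (("SA",), False),
    ]
    for i in range(1, 21):
        strategy = "custom" if i <= 10 else "average"
        within = (i - 1) % 10
        fraction = ONE_TENTH if within < 5 else ONE_SEVENTH
        signals, lr = signal_cycle[within % 5]
        registry[f"IP{i}"] = TestConfig(
            test_id=f"IP{i}",
            task="IP",
            ow_strategy=strategy,
            fraction=fraction,
            source_signals=signals,
            lr_distinction=lr,
            train_fraction=0.85,
        )
    # Health-condition detection: always the average window; HD1-HD4 use a
    # 1/7 window and HD5-HD8 a 1/10 window, alternating SP+SV / SP+SV+SEA
    # and the arm distinction off/on.
    hd_cycle = [
        (("SP", "SV"), False),
        (("SP", "SV"), True),
        (("SP", "SV", "SEA"), False),
        (("SP", "SV", "SEA"), True),
    ]
    for i in range(1, 9):
        fraction = ONE_SEVENTH if i <= 4 else ONE_TENTH
        signals, lr = hd_cycle[(i - 1) % 4]
        registry[f"HD{i}"] = TestConfig(
            test_id=f"HD{i}",
            task="HD",
            ow_strategy="average",
            fraction=fraction,
            source_signals=signals,
            lr_distinction=lr,
            train_fraction=0.90,
        )
    return registry


REGISTRY: Dict[str, TestConfig] = _build_registry()


def get_test_config(test_id: str) -> TestConfig:
    """Look up a registry row; unknown ids list the valid ones."""
    try:
        return REGISTRY[test_id]
    except KeyError:
        raise LookupError(
            f"unknown test id {test_id!r}; valid ids: IP1..IP20, HD1..HD8"
        ) from None


@dataclass
class PreparedTrial:
    """One recording after segmentation and normalization, with cached
    full-length feature channels for all four source signals."""

    recording: TrajectoryRecording
    segmentation: SegmentationResult
    motion_duration: float          # seconds
    channels: Dict[str, np.ndarray]


@dataclass
class PreparedDataset:
    """Segmented, normalized cohort ready for feature extraction."""

    trials: List[PreparedTrial]
    fs: float

    def subset(self, population: str) -> "PreparedDataset":
        if population not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}")
        if population == "all":
            return self
        keep = (
            (lambda c: c == "healthy")
            if population == "healthy"
            else (lambda c: c != "healthy")
        )
        trials = [t for t in self.trials if keep(t.recording.condition)]
        return PreparedDataset(trials=trials, fs=self.fs)

    @property
    def durations(self) -> np.ndarray:
        return np.array([t.motion_duration for t in self.trials])


def prepare_dataset(
    recordings: Sequence[TrajectoryRecording],
    params: SegmentationParams = SegmentationParams(),
    fc: float = 3.0,
    order: int = 4,
) -> PreparedDataset:
    """Segment every trial, normalize per subject, cache feature channels."""
    if len(recordings) == 0:
        raise ConfigurationError("dataset is empty")
    fs = recordings[0].fs
    by_subject: Dict[str, List[TrajectoryRecording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)

    trials: List[PreparedTrial] = []
    for subject_recs in by_subject.values():
        ref = anthropometric_reference(subject_recs)
        for rec in subject_recs:
            seg = segment_motion(hand_speed(rec, fc, order), params)
            norm = normalize_recording(rec, ref)
            trials.append(
                PreparedTrial(
                    recording=norm,
                    segmentation=seg,
                    motion_duration=(seg.end_idx - seg.start_idx + 1) / fs,
                    channels=compute_channels(norm, fc=fc, order=order),
                )
            )
    return PreparedDataset(trials=trials, fs=fs)


@dataclass
class RunReport:
    """Everything needed to interpret (and re-run) one test."""

    test_id: str
    algorithm: str
    population: str
    result: EvaluationResult
    ow_spec: ObservationWindowSpec
    n_features: int
    n_trials: int
    seed: int
    config: TestConfig

    def summary_row(self) -> Dict[str, object]:
        return {
            "test_id": self.test_id,
            "algorithm": self.algorithm,
            "population": self.population,
            "ow_strategy": self.ow_spec.strategy,
            "ow_fraction": str(self.ow_spec.fraction),
            "ow_samples": self.ow_spec.resolved_samples,
            "no_lr": not self.config.lr_distinction,
            "n_features": self.n_features,
            "n_trials": self.n_trials,
            "mean_accuracy": self.result.mean_accuracy,
            "sd_accuracy": self.result.sd_accuracy,
            "oob_mean": self.result.oob_mean,
            "oob_sd": self.result.oob_sd,
            "n_repeats": self.result.n_repeats,
            "seed": self.seed,
        }

    def save(self, path: str) -> str:
        """Persist the run parameters and per-repeat accuracies as JSON."""
        payload = dict(self.summary_row())
        payload["accuracies"] = self.result.accuracies.tolist()
        if self.result.oob_accuracies is not None:
            payload["oob_accuracies"] = self.result.oob_accuracies.tolist()
        payload["source_signals"] = list(self.config.source_signals)
        payload["train_fraction"] = self.config.train_fraction
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        return path


def build_features(
    dataset: PreparedDataset, config: TestConfig
) -> Tuple[pd.DataFrame, ObservationWindowSpec]:
    """Resolve the observation window and extract the feature table.

    The average strategy fixes one global sample count from the dataset-mean
    motion duration; the custom strategy sizes the window per trial. A
    window longer than a particular trial's motion segment is clipped to
    that segment (short trials would otherwise be unprocessable under the
    average strategy).
    """
    if len(dataset.trials) == 0:
        raise ConfigurationError("no trials left after population filtering")
    fs = dataset.fs
    if config.ow_strategy == "average":
        samples = average_window_samples(dataset.durations, config.fraction, fs)
    else:
        samples = 0  # resolved per trial below
    vectors = []
    per_trial_samples = []
    for trial in dataset.trials:
        if config.ow_strategy == "custom":
            ow = custom_window_samples(trial.motion_duration, config.fraction, fs)
        else:
            ow = samples
        motion_len = trial.segmentation.end_idx - trial.segmentation.start_idx + 1
        ow = max(min(ow, motion_len), 2)
        per_trial_samples.append(ow)
        vectors.append(
            features_from_channels(
                trial.channels,
                trial.recording,
                trial.segmentation,
                ow,
                config.source_signals,
            )
        )
    resolved = (
        samples
        if config.ow_strategy == "average"
        else int(round(float(np.mean(per_trial_samples))))
    )
    spec = ObservationWindowSpec(
        strategy=config.ow_strategy,
        fraction=config.fraction,
        resolved_samples=max(resolved, 2),
    )
    return feature_table(vectors), spec


def run_test(
    test_id: str,
    dataset: Union[Sequence[TrajectoryRecording], PreparedDataset],
    algorithm: str,
    seed: int,
    *,
    n_repeats: int = 200,
    population: str = "all",
    log_dir: Optional[str] = None,
) -> RunReport:
    """Run one registry test end to end on a dataset.

    ``dataset`` may be raw recordings or an already-prepared dataset (reuse
    the latter when sweeping many tests). ``population`` restricts intention
    prediction to the healthy or pathological subset; health-condition
    detection requires all three conditions to be present.
    """
    config = get_test_config(test_id)
    if algorithm not in ALGORITHMS:
        raise ValueError(f"algorithm must be one of {ALGORITHMS}")
    if not isinstance(dataset, PreparedDataset):
        dataset = prepare_dataset(dataset)
    subset = dataset.subset(population)
    if len(subset.trials) == 0:
        raise ConfigurationError(
            f"population {population!r} leaves no trials for {test_id}"
        )
    if config.task == "HD":
        present = {t.recording.condition for t in subset.trials}
        if present != set(CONDITIONS):
            raise ConfigurationError(
                f"{test_id} needs all three conditions; dataset has {sorted(present)}"
            )

    table, ow_spec = build_features(subset, config)
    label_cols = ["target", "arm", "condition", "subject_id"]
    X = table.drop(columns=label_cols)
    y = config.label_scheme.labels(table)
    result = repeated_evaluation(
        X,
        y.to_numpy(),
        algorithm,
        config.train_fraction,
        n_repeats=n_repeats,
        seed=seed,
        n_trees=config.n_trees,
    )
    report = RunReport(
        test_id=test_id,
        algorithm=algorithm,
        population=population,
        result=result,
        ow_spec=ow_spec,
        n_features=X.shape[1],
        n_trials=len(subset.trials),
        seed=int(seed),
        config=config,
    )
    if log_dir is not None:
        os.makedirs(log_dir, exist_ok=True)
        report.save(
            os.path.join(log_dir, f"{test_id}_{algorithm}_{population}.json")
        )
    return report


def run_matrix(
    test_ids: Sequence[str],
    dataset: Union[Sequence[TrajectoryRecording], PreparedDataset],
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
    *,
    n_repeats: int = 200,
    populations: Optional[Sequence[str]] = None,
    log_dir: Optional[str] = None,
) -> pd.DataFrame:
    """Run a battery of tests and return one summary row per combination.

    Intention-prediction tests default to the three population subsets
    (all/healthy/pathological); health-condition tests run on the complete
    dataset only.
    """
    if len(test_ids) == 0:
        raise ValueError("at least one test id is required")
    if not isinstance(dataset, PreparedDataset):
        dataset = prepare_dataset(dataset)
    rows = []
    for test_id in test_ids:
        config = get_test_config(test_id)
        if config.task == "IP":
            pops = populations if populations is not None else POPULATIONS
        else:
            pops = ("all",)
        for algorithm in algorithms:
            for population in pops:
                report = run_test(
                    test_id,
                    dataset,
                    algorithm,
                    seed,
                    n_repeats=n_repeats,
                    population=population,
                    log_dir=log_dir,
                )
                rows.append(report.summary_row())
    return pd.DataFrame(rows)
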