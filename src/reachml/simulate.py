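"""Synthetic multi-sensor reaching recordings.

The clinical dataset this pipeline was designed for (seated reaching to nine
targets, tracked with four electromagnetic sensors at 30 Hz) is not publicly
available, so this module generates a synthetic stand-in with the same
protocol structure: a standardized nine-target sequence, three cycles per arm
per subject, healthy subjects and post-stroke patients with left- or
right-hemisphere damage (LHD / RHD), and tracker-grade measurement noise
(0.8 mm RMS per position axis, 0.15 deg per orientation axis).

Hand trajectories follow a minimum-jerk profile — the standard model of
healthy point-to-point reaching. Pathological movement of the contralesional
arm is slower (duration scaled by ``1 + severity``), fragmented by corrective
sub-movements that produce a multi-peaked speed profile, and laterally curved
with a side-dependent bias. Each subject additionally carries an idiosyncratic
kinematic signature (sensor-mounting angle offsets, angle-ramp gain,
preferred speed), as real subjects do.

Coordinate frame: origin at the right-shoulder rest position, X to the
subject's right, Y anterior, Z up, millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import EmptyCohortError

#: Standardized target-presentation order (close/far/high x middle/internal/external).
TARGET_SEQUENCE: Tuple[str, ...] = (
    "CM", "FI", "HE", "FM", "CE", "HI", "CI", "FE", "HM",
)

CONDITIONS: Tuple[str, ...] = ("healthy", "LHD", "RHD")
SENSORS: Tuple[str, ...] = ("hand", "arm", "shoulder", "trunk")
ARMS: Tuple[str, ...] = ("L", "R")

#: Radial distance of close / far targets as a fraction of upper-limb length.
CLOSE_FRACTION = 0.65
FAR_FRACTION = 0.90
#: Height of the six low targets above the table plane [mm].
LOW_TARGET_HEIGHT = 70.0

#: Reference limb length [mm] used to scale body geometry.
_REF_LIMB = 750.0
#: Biacromial (shoulder-to-shoulder) width at reference scale [mm].
_SHOULDER_WIDTH = 380.0

_DEFAULT_FS = 30.0
_POSITION_NOISE_SD = 0.8   # mm, per axis (tracker static accuracy)
_ANGLE_NOISE_SD = 0.15     # deg, per axis


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile ``10 t^3 - 15 t^4 + 6 t^5`` on [0, 1]."""
    tau = np.asarray(tau, dtype=float)
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


@dataclass(frozen=True)
class TargetLayout:
    """Nine reaching targets in the shoulder-origin frame.

    ``targets`` maps the nine standard labels to 3-D coordinates [mm].
    Radial distances are measured in the table-parallel plane from the
    vertical axis through the shoulder; close targets sit at 65% and far
    targets at 90% of the upper-limb length. Low targets are 70 mm above the
    table, high targets at acromion height vertically above the matching far
    target.
    """

    limb_length: float
    acromion_height: float
    targets: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.targets) != set(TARGET_SEQUENCE):
            raise ValueError("layout must contain exactly the 9 standard targets")


def make_target_layout(limb_length: float, acromion_height: float) -> TargetLayout:
    """Build the nine-target layout for one subject.

    Parameters
    ----------
    limb_length:
        Equivalent upper-limb length (acromion to pointer tip) [mm].
    acromion_height:
        Height of the acromion above the table plane [mm]; must exceed the
        70 mm low-target height.
    """
    if limb_length <= 0:
        raise ValueError(f"limb_length must be positive, got {limb_length}")
    if acromion_height <= LOW_TARGET_HEIGHT:
        raise ValueError(
            f"acromion_height must exceed {LOW_TARGET_HEIGHT} mm, got {acromion_height}"
        )
    # Horizontal unit vectors: middle = parasagittal (anterior); internal is
    # rotated 45 deg toward the body midline (toward -X for the right arm),
    # external 45 deg away.
    s = np.sin(np.deg2rad(45.0))
    directions = {
        "M": np.array([0.0, 1.0]),
        "I": np.array([-s, s]),
        "E": np.array([s, s]),
    }
    z_low = LOW_TARGET_HEIGHT - acromion_height   # shoulder-origin frame
    z_high = 0.0
    targets: Dict[str, np.ndarray] = {}
    for dir_label, d in directions.items():
        close = CLOSE_FRACTION * limb_length * d
        far = FAR_FRACTION * limb_length * d
        targets["C" + dir_label] = np.array([close[0], close[1], z_low])
        targets["F" + dir_label] = np.array([far[0], far[1], z_low])
        targets["H" + dir_label] = np.array([far[0], far[1], z_high])
    return TargetLayout(float(limb_length), float(acromion_height), targets)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject simulation parameters.

    ``pathology_severity`` is a dimensionless scalar in [0, 1]; zero if and
    only if the subject is healthy. ``rng_seed`` seeds the subject's
    idiosyncratic kinematic signature so it is stable across trials.
    """

    subject_id: str
    condition: str
    handedness: str
    limb_length: float
    mean_movement_duration: float
    pathology_severity: float
    rng_seed: int
    acromion_height: float = 450.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.handedness not in ARMS:
            raise ValueError(f"handedness must be 'L' or 'R', got {self.handedness!r}")
        if self.mean_movement_duration <= 0:
            raise ValueError("mean_movement_duration must be positive")
        if not 0.0 <= self.pathology_severity <= 1.0:
            raise ValueError("pathology_severity must lie in [0, 1]")
        if (self.pathology_severity == 0.0) != (self.condition == "healthy"):
            raise ValueError(
                "pathology_severity must be 0 iff condition is 'healthy'"
            )


@dataclass
class TrajectoryRecording:
    """One trial's four-sensor position and Euler-angle streams.

    ``positions[sensor]`` is an (N, 3) array [mm] and ``angles[sensor]`` an
    (N, 3) array [deg] for each of hand, arm, shoulder, trunk. Ground-truth
    motion onset/offset indices are present for simulated data only.
    """

    subject_id: str
    arm: str
    target_label: str
    condition: str
    fs: float
    timestamps: np.ndarray
    positions: Dict[str, np.ndarray]
    angles: Dict[str, np.ndarray]
    true_onset_idx: Optional[int] = None
    true_offset_idx: Optional[int] = None

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.shape[0])

    def validate(self) -> None:
        """Check stream-consistency invariants; raise ``ValueError`` on failure."""
        n = self.n_samples
        if n < 40:
            raise ValueError(f"recording too short: {n} samples (minimum 40)")
        for sensor in SENSORS:
            if sensor not in self.positions or sensor not in self.angles:
                raise ValueError(f"missing streams for sensor {sensor!r}")
            for arr in (self.positions[sensor], self.angles[sensor]):
                if arr.shape != (n, 3):
                    raise ValueError(
                        f"stream shape mismatch for {sensor!r}: {arr.shape}"
                    )
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
            raise ValueError("timestamp spacing must equal 1/fs")
        if self.trunk_displacement() >= 5.0:
            raise ValueError(
                "trunk sensor moved >= 5 mm; the strap constraint is violated"
            )

    def trunk_displacement(self) -> float:
        """Distance [mm] between the trunk sensor's mean position in the
        leading and trailing 10-sample rest blocks."""
        trunk = self.positions["trunk"]
        return float(
            np.linalg.norm(trunk[:10].mean(axis=0) - trunk[-10:].mean(axis=0))
        )


def _body_geometry(profile: SubjectProfile) -> Dict[str, np.ndarray]:
    """Rest positions of the four sensors and both shoulders, scaled with
    the subject's limb length."""
    s = profile.limb_length / _REF_LIMB
    h = profile.acromion_height
    right_shoulder = np.zeros(3)
    left_shoulder = np.array([-_SHOULDER_WIDTH * s, 0.0, 0.0])
    return {
        "right_shoulder": right_shoulder,
        "left_shoulder": left_shoulder,
        # offsets relative to the active shoulder
        "hand_offset": np.array([0.0, 150.0 * s, 30.0 * s - h]),
        "arm_offset": np.array([0.0, 30.0 * s, -110.0 * s]),
        # trunk (manubrium) is mid-line, independent of the active arm
        "trunk": np.array([-_SHOULDER_WIDTH * s / 2.0, 40.0 * s, -120.0 * s]),
    }


def _angle_deltas(
    target_label: str, arm: str, layout: TargetLayout, profile: SubjectProfile,
    gain: float,
) -> Dict[str, np.ndarray]:
    """Target-dependent Euler-angle excursions [deg] for each sensor.

    Yaw (alpha) tracks the reach azimuth, pitch (beta) the target elevation
    and distance, roll (gamma) the distance with a small azimuth coupling.
    Mirror-odd components (alpha, gamma) flip sign for the left arm, which
    makes the two arms distinguishable from orientation data alone. The
    shoulder ramp is small and target-independent; the trunk does not rotate.
    """
    azimuth = {"M": 0.0, "I": -45.0, "E": 45.0}[target_label[1]]
    target = layout.targets[target_label]
    r_frac = float(np.hypot(target[0], target[1])) / profile.limb_length
    dz = target[2] - (-profile.acromion_height + 30.0)   # vs hand rest height
    d_alpha = 0.5 * azimuth * gain
    d_beta = (30.0 * dz / profile.limb_length + 12.0 * r_frac) * gain
    d_gamma = (20.0 * r_frac + 5.0 * azimuth / 45.0) * gain
    mirror = -1.0 if arm == "L" else 1.0
    hand = np.array([mirror * d_alpha, d_beta, mirror * d_gamma])
    return {
        "hand": hand,
        "arm": 0.5 * hand,
        "shoulder": np.array([0.0, 2.0, 0.0]),
        "trunk": np.zeros(3),
    }


def simulate_trial(
    profile: SubjectProfile,
    layout: TargetLayout,
    target_label: str,
    arm: str,
    seed: int,
    *,
    fs: float = _DEFAULT_FS,
    noise: bool = True,
    position_noise_sd: float = _POSITION_NOISE_SD,
    angle_noise_sd: float = _ANGLE_NOISE_SD,
) -> TrajectoryRecording:
    """Simulate one reaching trial.

    The hand travels from the start cross (on the table, in line with the
    shoulder) to the requested target along a minimum-jerk path, padded with
    15-30 rest samples on either side. The humerus sensor moves 50% of the
    hand displacement, the shoulder sensor 5%, the trunk sensor stays put.
    The same ``seed`` reproduces the trial bit-identically.
    """
    if target_label not in layout.targets:
        raise ValueError(
            f"unknown target {target_label!r}; expected one of {TARGET_SEQUENCE}"
        )
    if arm not in ARMS:
        raise ValueError(f"arm must be 'L' or 'R', got {arm!r}")
    rng = np.random.default_rng(int(seed))
    style = np.random.default_rng(int(profile.rng_seed))
    # Subject signature: sensor-mounting angle offsets and ramp gain. Fixed
    # draw order keeps the signature stable across trials.
    angle_offsets = {
        "hand": style.uniform(-10.0, 10.0, 3),
        "arm": style.uniform(-10.0, 10.0, 3),
        "shoulder": style.uniform(-3.0, 3.0, 3),
        "trunk": np.zeros(3),
    }
    angle_gain = float(style.uniform(0.85, 1.15))

    geom = _body_geometry(profile)
    scale = profile.limb_length / _REF_LIMB
    shoulder0 = geom["left_shoulder"] if arm == "L" else geom["right_shoulder"]
    mirror = np.array([-1.0, 1.0, 1.0]) if arm == "L" else np.ones(3)
    target_world = shoulder0 + mirror * layout.targets[target_label]
    hand0 = shoulder0 + mirror * geom["hand_offset"]
    arm0 = shoulder0 + mirror * geom["arm_offset"]

    impaired = (profile.condition == "LHD" and arm == "R") or (
        profile.condition == "RHD" and arm == "L"
    )
    severity = profile.pathology_severity if impaired else 0.0

    duration = (
        profile.mean_movement_duration
        * (1.0 + severity)
        * float(rng.uniform(0.9, 1.1))
    )
    n_motion = max(int(round(duration * fs)), 12)
    rest_pre = int(rng.integers(15, 31))
    rest_post = int(rng.integers(15, 31))
    n = rest_pre + n_motion + rest_post

    tau = np.arange(1, n_motion + 1) / n_motion
    mj = minimum_jerk(tau)
    path = hand0 + mj[:, None] * (target_world - hand0)

    if severity > 0.0:
        # Lateral curvature bias, sign set by the damaged hemisphere.
        side_sign = 1.0 if profile.condition == "LHD" else -1.0
        d_h = target_world - hand0
        horiz = np.array([d_h[0], d_h[1], 0.0])
        nrm = np.linalg.norm(horiz)
        perp = (
            np.array([-horiz[1], horiz[0], 0.0]) / nrm
            if nrm > 1e-9
            else np.array([1.0, 0.0, 0.0])
        )
        path = path + (
            40.0 * severity * scale * side_sign
        ) * np.sin(np.pi * tau)[:, None] * perp
        # Corrective sub-movements: localized minimum-jerk-like pulses that
        # fragment the speed profile into multiple peaks.
        for _ in range(int(rng.integers(2, 5))):
            centre = float(rng.uniform(0.25, 0.75))
            width = float(rng.uniform(0.08, 0.15))
            direction = rng.normal(0.0, 1.0, 3)
            direction /= np.linalg.norm(direction)
            amp = severity * float(rng.uniform(15.0, 35.0)) * scale
            u = np.clip((tau - (centre - width)) / (2.0 * width), 0.0, 1.0)
            bump = (4.0 * u * (1.0 - u)) ** 3
            path = path + amp * bump[:, None] * direction

    hand_disp = path - hand0
    positions = {
        "hand": np.concatenate(
            [np.tile(hand0, (rest_pre, 1)), path, np.tile(path[-1], (rest_post, 1))]
        ),
        "arm": None,
        "shoulder": None,
        "trunk": np.tile(geom["trunk"], (n, 1)),
    }
    for sensor, frac in (("arm", 0.5), ("shoulder", 0.05)):
        base = arm0 if sensor == "arm" else shoulder0
        moving = base + frac * hand_disp
        positions[sensor] = np.concatenate(
            [np.tile(base, (rest_pre, 1)), moving, np.tile(moving[-1], (rest_post, 1))]
        )

    # Orientation ramps lead the hand (pre-shaping): the ramp completes by
    # mid-movement, following a compressed minimum-jerk time course.
    ramp = minimum_jerk(np.clip(tau / 0.5, 0.0, 1.0))
    deltas = _angle_deltas(target_label, arm, layout, profile, angle_gain)
    angles = {}
    for sensor in SENSORS:
        rest_val = angle_offsets[sensor]
        course = rest_val + np.outer(ramp, deltas[sensor])
        angles[sensor] = np.concatenate(
            [np.tile(rest_val, (rest_pre, 1)), course, np.tile(course[-1], (rest_post, 1))]
        )

    if noise:
        for sensor in SENSORS:
            positions[sensor] = positions[sensor] + rng.normal(
                0.0, position_noise_sd, (n, 3)
            )
        for sensor in SENSORS:
            angles[sensor] = angles[sensor] + rng.normal(0.0, angle_noise_sd, (n, 3))

    rec = TrajectoryRecording(
        subject_id=profile.subject_id,
        arm=arm,
        target_label=target_label,
        condition=profile.condition,
        fs=float(fs),
        timestamps=np.arange(n) / float(fs),
        positions=positions,
        angles=angles,
        true_onset_idx=rest_pre,
        true_offset_idx=rest_pre + n_motion - 1,
    )
    rec.validate()
    return rec


def _make_subjects(
    n_healthy: int, n_lhd: int, n_rhd: int, severity: float, master: np.random.Generator
) -> List[SubjectProfile]:
    subjects = []
    for condition, count, prefix in (
        ("healthy", n_healthy, "H"),
        ("LHD", n_lhd, "L"),
        ("RHD", n_rhd, "R"),
    ):
        for i in range(count):
            limb = float(np.clip(master.normal(_REF_LIMB, 40.0), 600.0, 900.0))
            acromion = float(np.clip(master.normal(450.0, 30.0), 350.0, 550.0))
            dur = float(np.clip(master.normal(2.2, 0.25), 1.6, 3.0))
            sev = (
                0.0
                if condition == "healthy"
                else float(np.clip(master.normal(severity, 0.1), 0.05, 1.0))
            )
            handed = "L" if master.uniform() < 0.1 else "R"
            subjects.append(
                SubjectProfile(
                    subject_id=f"{prefix}{i + 1:02d}",
                    condition=condition,
                    handedness=handed,
                    limb_length=limb,
                    mean_movement_duration=dur,
                    pathology_severity=sev,
                    rng_seed=int(master.integers(0, 2**31)),
                    acromion_height=acromion,
                )
            )
    return subjects


def simulate_cohort(
    n_healthy: int,
    n_lhd: int,
    n_rhd: int,
    cycles_per_arm: int = 3,
    seed: int = 0,
    *,
    severity: float = 0.6,
    fs: float = _DEFAULT_FS,
    noise: bool = True,
) -> Tuple[List[TrajectoryRecording], pd.DataFrame]:
    """Simulate a full cohort.

    Each subject performs ``cycles_per_arm`` cycles with the left arm then
    the right arm; each cycle visits all nine targets in the standardized
    order, giving ``subjects x 2 x cycles_per_arm x 9`` recordings. Returns
    the recordings and a manifest table (one row per trial, ``file`` column
    left empty until the cohort is written to disk).
    """
    for name, v in (("n_healthy", n_healthy), ("n_lhd", n_lhd), ("n_rhd", n_rhd)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if cycles_per_arm < 1:
        raise ValueError("cycles_per_arm must be >= 1")
    if n_healthy + n_lhd + n_rhd == 0:
        raise EmptyCohortError("cohort has no subjects")

    master = np.random.default_rng(int(seed))
    subjects = _make_subjects(n_healthy, n_lhd, n_rhd, severity, master)

    recordings: List[TrajectoryRecording] = []
    rows = []
    for profile in subjects:
        layout = make_target_layout(profile.limb_length, profile.acromion_height)
        for arm in ("L", "R"):
            for cycle in range(1, cycles_per_arm + 1):
                for target in TARGET_SEQUENCE:
                    trial_seed = int(master.integers(0, 2**31))
                    rec = simulate_trial(
                        profile, layout, target, arm, trial_seed, fs=fs, noise=noise
                    )
                    recordings.append(rec)
                    rows.append(
                        {
                            "subject_id": profile.subject_id,
                            "condition": profile.condition,
                            "handedness": profile.handedness,
                            "arm": arm,
                            "target": target,
                            "cycle": cycle,
                            "file": "",
                            "true_onset_idx": rec.true_onset_idx,
                            "true_offset_idx": rec.true_offset_idx,
                        }
                    )
    return recordings, pd.DataFrame(rows)
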