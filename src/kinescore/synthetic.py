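"""Synthetic multi-class exercise motion generator.

Produces labeled, quality-scored 20-joint skeleton sequences so the whole
pipeline (training, labeling, scoring) can be exercised end to end without a
depth sensor.  Motions are built by forward kinematics on a fixed-bone-length
skeleton: each exercise is a program of sinusoidal joint-angle trajectories
on a subset of rotation channels (shoulders, elbows, hips, knees, spine) plus
an optional vertical bob of the pelvis.  Between-class separation comes from
which limbs move and at which frequencies/amplitudes.

Execution realism knobs:

* ``speed`` scales all frequencies (temporal contraction/expansion),
* ``phase`` shifts the whole program,
* ``quality`` q in [0, 100] is the ground-truth coach score: q < 100 shrinks
  movement amplitudes, adds slow Ornstein-Uhlenbeck form drift, and puts the
  joint-angle channels systematically out of time with each other; the
  degradation scales grow with sqrt(100 - q) so that independent execution
  faults accumulate linearly in variance,
* ``noise_sigma`` is isotropic Gaussian position noise emulating the jitter
  of depth-derived skeletons.

Background (non-exercise) spans model idle time between sets: a small
Ornstein-Uhlenbeck postural sway on every rotation channel plus sporadic
raised-cosine gesture bursts on a few random channels -- realistic
negatives for the unclassified class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .skeleton import (
    CANONICAL_JOINT_MAP,
    N_JOINTS,
    LabelSegment,
    LabelTrack,
    SkeletonSequence,
    write_labels,
    write_sequence,
)

# ---------------------------------------------------------------------------
# skeleton rig

#: joint -> (parent, rest offset in the parent frame, meters)
SKELETON_TREE: dict[str, tuple[str | None, tuple[float, float, float]]] = {
    "hip_center": (None, (0.0, 1.00, 0.0)),
    "spine": ("hip_center", (0.0, 0.22, 0.0)),
    "shoulder_center": ("spine", (0.0, 0.24, 0.0)),
    "head": ("shoulder_center", (0.0, 0.26, 0.0)),
    "shoulder_left": ("shoulder_center", (-0.19, -0.02, 0.0)),
    "shoulder_right": ("shoulder_center", (0.19, -0.02, 0.0)),
    "elbow_left": ("shoulder_left", (0.0, -0.28, 0.0)),
    "elbow_right": ("shoulder_right", (0.0, -0.28, 0.0)),
    "wrist_left": ("elbow_left", (0.0, -0.25, 0.0)),
    "wrist_right": ("elbow_right", (0.0, -0.25, 0.0)),
    "hand_left": ("wrist_left", (0.0, -0.08, 0.0)),
    "hand_right": ("wrist_right", (0.0, -0.08, 0.0)),
    "hip_left": ("hip_center", (-0.10, -0.02, 0.0)),
    "hip_right": ("hip_center", (0.10, -0.02, 0.0)),
    "knee_left": ("hip_left", (0.0, -0.42, 0.0)),
    "knee_right": ("hip_right", (0.0, -0.42, 0.0)),
    "ankle_left": ("knee_left", (0.0, -0.40, 0.0)),
    "ankle_right": ("knee_right", (0.0, -0.40, 0.0)),
    "foot_left": ("ankle_left", (0.0, -0.04, 0.14)),
    "foot_right": ("ankle_right", (0.0, -0.04, 0.14)),
}

#: rotation channel -> (joint it drives, axis, sign); angles in degrees
ROTATION_CHANNELS: dict[str, tuple[str, str, float]] = {
    "shoulder_l_abd": ("shoulder_left", "z", -1.0),
    "shoulder_r_abd": ("shoulder_right", "z", 1.0),
    "shoulder_l_flex": ("shoulder_left", "x", -1.0),
    "shoulder_r_flex": ("shoulder_right", "x", -1.0),
    "elbow_l_flex": ("elbow_left", "x", -1.0),
    "elbow_r_flex": ("elbow_right", "x", -1.0),
    "hip_l_abd": ("hip_left", "z", -1.0),
    "hip_r_abd": ("hip_right", "z", 1.0),
    "hip_l_flex": ("hip_left", "x", -1.0),
    "hip_r_flex": ("hip_right", "x", -1.0),
    "knee_l_flex": ("knee_left", "x", 1.0),
    "knee_r_flex": ("knee_right", "x", 1.0),
    "spine_twist": ("spine", "y", 1.0),
    "spine_side": ("spine", "z", 1.0),
    "spine_fwd": ("spine", "x", 1.0),
}

#: neutral stance: slight arm abduction and elbow bend to avoid exactly
#: collinear limb chains at rest
BASE_POSTURE: dict[str, float] = {
    "shoulder_l_abd": 12.0,
    "shoulder_r_abd": 12.0,
    "elbow_l_flex": 8.0,
    "elbow_r_flex": 8.0,
}

_TOPO_ORDER = list(SKELETON_TREE)  # insertion order is parent-before-child


# ---------------------------------------------------------------------------
# programs


@dataclass(frozen=True)
class Sinusoid:
    amp: float  # degrees (or meters for root_y)
    freq: float  # Hz
    phase: float = 0.0  # radians


@dataclass(frozen=True)
class ExerciseProgram:
    """Class-specific periodic joint-angle program."""

    class_id: int
    name: str
    channels: dict[str, list[Sinusoid]] = field(default_factory=dict)
    base: dict[str, float] = field(default_factory=dict)
    root_bob: list[Sinusoid] = field(default_factory=list)  # meters, vertical
    root_base: float = 0.0


def _p(class_id: int, name: str, channels, base=None, root_bob=(), root_base=0.0):
    return ExerciseProgram(
        class_id,
        name,
        {k: list(v) for k, v in channels.items()},
        dict(base or {}),
        list(root_bob),
        root_base,
    )


DEFAULT_PROGRAMS: list[ExerciseProgram] = [
    _p(
        1,
        "jumping_jacks",
        {
            "shoulder_l_abd": [Sinusoid(65, 0.8)],
            "shoulder_r_abd": [Sinusoid(65, 0.8)],
            "hip_l_abd": [Sinusoid(14, 0.8)],
            "hip_r_abd": [Sinusoid(14, 0.8)],
        },
        base={"shoulder_l_abd": 75, "shoulder_r_abd": 75, "hip_l_abd": 14, "hip_r_abd": 14},
        root_bob=[Sinusoid(0.03, 1.6)],
    ),
    _p(
        2,
        "squats",
        {
            "knee_l_flex": [Sinusoid(42, 0.4)],
            "knee_r_flex": [Sinusoid(42, 0.4)],
            "hip_l_flex": [Sinusoid(36, 0.4)],
            "hip_r_flex": [Sinusoid(36, 0.4)],
            "spine_fwd": [Sinusoid(10, 0.4)],
        },
        base={"knee_l_flex": 46, "knee_r_flex": 46, "hip_l_flex": 40, "hip_r_flex": 40, "spine_fwd": 12},
        root_bob=[Sinusoid(-0.09, 0.4)],
        root_base=-0.09,
    ),
    _p(
        3,
        "toe_touch_kicks",
        {
            "hip_l_flex": [Sinusoid(38, 0.5)],
            "hip_r_flex": [Sinusoid(38, 0.5, np.pi)],
            "shoulder_r_flex": [Sinusoid(45, 0.5)],
            "shoulder_l_flex": [Sinusoid(45, 0.5, np.pi)],
        },
        base={
            "hip_l_flex": 28,
            "hip_r_flex": 28,
            "shoulder_l_flex": 40,
            "shoulder_r_flex": 40,
        },
    ),
    _p(
        4,
        "windmills",
        {
            "spine_fwd": [Sinusoid(28, 0.3)],
            "spine_side": [Sinusoid(24, 0.3, np.pi / 2)],
            "shoulder_l_flex": [Sinusoid(40, 0.3)],
            "shoulder_r_flex": [Sinusoid(40, 0.3, np.pi)],
        },
        base={"spine_fwd": 30, "shoulder_l_flex": 45, "shoulder_r_flex": 45},
    ),
    _p(
        5,
        "biceps_curls",
        {
            "elbow_l_flex": [Sinusoid(55, 0.7)],
            "elbow_r_flex": [Sinusoid(55, 0.7)],
            "shoulder_l_flex": [Sinusoid(9, 0.7)],
            "shoulder_r_flex": [Sinusoid(9, 0.7)],
        },
        base={"elbow_l_flex": 65, "elbow_r_flex": 65, "shoulder_l_flex": 12, "shoulder_r_flex": 12},
    ),
    _p(
        6,
        "overhead_press",
        {
            "shoulder_l_abd": [Sinusoid(45, 0.55)],
            "shoulder_r_abd": [Sinusoid(45, 0.55)],
            "elbow_l_flex": [Sinusoid(40, 0.55, np.pi)],
            "elbow_r_flex": [Sinusoid(40, 0.55, np.pi)],
        },
        base={
            "shoulder_l_abd": 125,
            "shoulder_r_abd": 125,
            "elbow_l_flex": 45,
            "elbow_r_flex": 45,
        },
    ),
    _p(
        7,
        "side_bends",
        {
            "spine_side": [Sinusoid(26, 0.3)],
            "shoulder_l_abd": [Sinusoid(18, 0.3)],
            "shoulder_r_abd": [Sinusoid(18, 0.3, np.pi)],
        },
        base={"shoulder_l_abd": 28, "shoulder_r_abd": 28},
    ),
    _p(
        8,
        "high_knees",
        {
            "hip_l_flex": [Sinusoid(35, 0.9)],
            "hip_r_flex": [Sinusoid(35, 0.9, np.pi)],
            "knee_l_flex": [Sinusoid(30, 0.9)],
            "knee_r_flex": [Sinusoid(30, 0.9, np.pi)],
        },
        base={"hip_l_flex": 32, "hip_r_flex": 32, "knee_l_flex": 28, "knee_r_flex": 28},
        root_bob=[Sinusoid(0.015, 1.8)],
    ),
    _p(
        9,
        "toe_touches",
        {
            "spine_fwd": [Sinusoid(34, 0.25)],
            "shoulder_l_flex": [Sinusoid(45, 0.25)],
            "shoulder_r_flex": [Sinusoid(45, 0.25)],
        },
        base={"spine_fwd": 36, "shoulder_l_flex": 50, "shoulder_r_flex": 50},
    ),
]


@dataclass(frozen=True)
class ExecutionParams:
    """Per-execution variability: tempo, phase, quality and sensor noise."""

    speed: float = 1.0  # in [0.7, 1.3]
    phase: float = 0.0  # radians, [0, 2 pi)
    noise_sigma: float = 0.008  # meters, per-joint jitter of depth-derived skeletons
    quality: float = 100.0  # ground-truth coach score
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.quality <= 100.0:
            raise ValueError("quality must lie in [0, 100]")
        if self.speed <= 0:
            raise ValueError("speed must be positive")


# quality -> degradation mapping (linear by construction, so the generator's
# ground-truth score is unambiguous): a low coach score means reduced range
# of motion, shaky/drifting form, and limbs out of time with each other
_AMP_LOSS_PER_POINT = 0.0045  # amplitude multiplier 1 - 0.0045 (100 - q)
_JITTER_DEG_PER_SQRT_POINT = 0.9  # OU form-drift std 0.3 + 1.2 sqrt(100 - q) deg
_JITTER_BASE_DEG = 0.3
_JITTER_TAU = 2.0  # s; slow drift ("losing the form"), not frame noise
_PHASE_ERR_PER_SQRT_POINT = 0.011  # channel timing offset, turns per sqrt(point)


def _ou_series(rng: np.random.Generator, n: int, dt: float, sigma: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path with std ``sigma`` and timescale ``tau``."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    a = np.exp(-dt / tau)
    b = sigma * np.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, 1.0, n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * eps[i - 1]
    return x


def _rot(axis: str, degrees: np.ndarray) -> np.ndarray:
    """(T,3,3) rotation matrices about a principal axis."""
    return Rotation.from_euler(
        axis, np.asarray(degrees, float).reshape(-1, 1), degrees=True
    ).as_matrix()


def forward_kinematics(
    channel_angles: dict[str, np.ndarray], root_y: np.ndarray | float = 0.0
) -> np.ndarray:
    """Pose the rig for T frames; returns (T, 20, 3) in canonical joint order.

    ``channel_angles`` maps rotation channels to per-frame angles (degrees);
    missing channels are held at zero.  Bone lengths are exact by
    construction.  ``root_y`` offsets the pelvis vertically (meters).
    """
    lengths = {len(v) for v in channel_angles.values() if np.ndim(v) > 0}
    if not lengths:
        raise ValueError("at least one channel must provide a time axis")
    T = lengths.pop()
    if lengths:
        raise ValueError("all channels must share the same length")
    by_joint: dict[str, list[tuple[str, np.ndarray]]] = {}
    for chan, angles in channel_angles.items():
        joint, axis, sign = ROTATION_CHANNELS[chan]
        by_joint.setdefault(joint, []).append((axis, sign * np.asarray(angles, float)))
    eye = np.broadcast_to(np.eye(3), (T, 3, 3))
    R_world: dict[str, np.ndarray] = {}
    pos: dict[str, np.ndarray] = {}
    for joint in _TOPO_ORDER:
        parent, offset = SKELETON_TREE[joint]
        local = eye
        for axis, angles in by_joint.get(joint, []):
            local = np.einsum("tij,tjk->tik", local, _rot(axis, angles))
        if parent is None:
            base = np.tile(np.asarray(offset, float), (T, 1))
            base[:, 1] += np.asarray(root_y, float)
            pos[joint] = base
            R_world[joint] = local
        else:
            pos[joint] = pos[parent] + np.einsum(
                "tij,j->ti", R_world[parent], np.asarray(offset, float)
            )
            R_world[joint] = np.einsum("tij,tjk->tik", R_world[parent], local)
    out = np.empty((T, N_JOINTS, 3))
    for idx, name in CANONICAL_JOINT_MAP.items():
        out[:, idx - 1] = pos[name]
    return out


def _program_angles(
    program: ExerciseProgram,
    t: np.ndarray,
    params: ExecutionParams,
    rng: np.random.Generator,
    fps: float,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Evaluate a program's channel trajectories with quality degradation."""
    deficit = 100.0 - params.quality
    amp_mult = max(0.0, 1.0 - _AMP_LOSS_PER_POINT * deficit)
    # independent execution faults accumulate linearly in variance, so both
    # degradation scales grow with the square root of the deficit
    jitter_std = _JITTER_BASE_DEG + _JITTER_DEG_PER_SQRT_POINT * np.sqrt(deficit)
    phase_err_std = 2 * np.pi * _PHASE_ERR_PER_SQRT_POINT * np.sqrt(deficit)
    angles: dict[str, np.ndarray] = {}
    active = set(program.channels) | set(program.base) | set(BASE_POSTURE)
    for n_chan, chan in enumerate(sorted(active)):
        base = program.base.get(chan, BASE_POSTURE.get(chan, 0.0))
        theta = np.full(len(t), float(base))
        # systematic exercise-specific timing fault: alternate channels lead/
        # lag by an offset proportional to the quality deficit
        chan_phase_err = phase_err_std * (1.0 if n_chan % 2 == 0 else -1.0)
        for s in program.channels.get(chan, []):
            theta = theta + amp_mult * s.amp * np.sin(
                2 * np.pi * s.freq * params.speed * t
                + s.phase + params.phase + chan_phase_err
            )
        theta = theta + _ou_series(rng, len(t), 1.0 / fps, jitter_std, _JITTER_TAU)
        angles[chan] = theta
    root_y = np.full(len(t), program.root_base * (amp_mult if program.root_base else 1.0))
    for s in program.root_bob:
        root_y = root_y + amp_mult * s.amp * np.sin(
            2 * np.pi * s.freq * params.speed * t + s.phase + params.phase
        )
    return angles, root_y


def generate_execution(
    program: ExerciseProgram,
    params: ExecutionParams,
    duration: float = 60.0,
    fps: float = 30.0,
) -> tuple[SkeletonSequence, int, float]:
    """One exercise execution; returns (sequence, class_id, ground-truth score).

    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    T = int(round(duration * fps))
    t = np.arange(T) / fps
    angles, root_y = _program_angles(program, t, params, rng, fps)
    xyz = forward_kinematics(angles, root_y)
    if params.noise_sigma > 0:
        xyz = xyz + rng.normal(0.0, params.noise_sigma, xyz.shape)
    seq = SkeletonSequence(
        t,
        xyz,
        np.ones((T, N_JOINTS), dtype=bool),
        fps,
        subject_id=f"{program.name}_q{params.quality:g}",
    )
    return seq, program.class_id, params.quality


def _background_angles(
    t: np.ndarray,
    rng: np.random.Generator,
    fps: float,
    sway_deg: float = 2.5,
    sway_tau: float = 2.0,
    gesture_rate: float = 1.0 / 6.0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Idle behavior between exercises: postural sway plus sporadic gestures.

    All channels carry a small Ornstein-Uhlenbeck sway; on top of it,
    gesture events (Poisson, ~one every six seconds) move one to three
    random channels through a brief raised-cosine excursion of up to ~45
    degrees -- reaching for things, shifting weight, waving.  Unlike an
    exercise, gestures are transient and uncoordinated across joints.
    """
    n = len(t)
    duration = n / fps
    channels = sorted(ROTATION_CHANNELS)
    angles = {
        chan: BASE_POSTURE.get(chan, 0.0)
        + _ou_series(rng, n, 1.0 / fps, sway_deg, sway_tau)
        for chan in channels
    }
    n_events = rng.poisson(gesture_rate * duration)
    for _ in range(n_events):
        t0 = rng.uniform(0.0, duration)
        width = rng.uniform(1.0, 3.0)
        k = rng.integers(1, 4)
        picked = rng.choice(len(channels), size=k, replace=False)
        env = np.zeros(n)
        inside = (t >= t0) & (t <= t0 + width)
        env[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - t0) / width))
        for ci in picked:
            amp = rng.uniform(10.0, 45.0) * rng.choice([-1.0, 1.0])
            angles[channels[ci]] = angles[channels[ci]] + amp * env
    root_y = _ou_series(rng, n, 1.0 / fps, 0.01, sway_tau)
    return angles, root_y


def generate_background(
    duration: float,
    fps: float = 30.0,
    seed: int = 0,
    noise_sigma: float = 0.008,
) -> SkeletonSequence:
    """Smooth non-exercise wander (negatives for the unclassified class)."""
    rng = np.random.default_rng(seed)
    T = int(round(duration * fps))
    t = np.arange(T) / fps
    angles, root_y = _background_angles(t, rng, fps)
    xyz = forward_kinematics(angles, root_y)
    if noise_sigma > 0:
        xyz = xyz + rng.normal(0.0, noise_sigma, xyz.shape)
    return SkeletonSequence(
        t, xyz, np.ones((T, N_JOINTS), dtype=bool), fps, subject_id="background"
    )


# ---------------------------------------------------------------------------
# dataset assembly

#: coach-score ladder assigned to the repetitions of each class, in order;
#: guarantees one perfect reference and a spread of imperfect ones
DEFAULT_QUALITY_LADDER = (100.0, 100.0, 95.0, 90.0, 85.0, 80.0, 75.0, 70.0, 65.0, 60.0)

_BLEND_S = 0.5  # raised-cosine ramp just outside each exercise segment


@dataclass
class DatasetItem:
    sequence: SkeletonSequence
    labels: LabelTrack
    class_id: int
    quality: float
    speed: float
    phase: float
    seed: int


def _blend_weight(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """1 inside [t0, t1], raised-cosine ramps over _BLEND_S just outside."""
    w = np.zeros_like(t)
    w[(t >= t0) & (t <= t1)] = 1.0
    pre = (t >= t0 - _BLEND_S) & (t < t0)
    w[pre] = 0.5 * (1 + np.cos(np.pi * (t0 - t[pre]) / _BLEND_S))
    post = (t > t1) & (t <= t1 + _BLEND_S)
    w[post] = 0.5 * (1 + np.cos(np.pi * (t[post] - t1) / _BLEND_S))
    return w


def _make_item(
    program: ExerciseProgram,
    params: ExecutionParams,
    duration: float,
    background_fraction: float,
    fps: float,
    rng: np.random.Generator,
) -> DatasetItem:
    total_bg = duration * background_fraction / max(1e-9, 1.0 - background_fraction)
    if background_fraction > 0:
        total_bg = max(total_bg, 2 * (_BLEND_S + 1.0 / fps))
        split = rng.uniform(0.35, 0.65)
        bg_before, bg_after = split * total_bg, (1 - split) * total_bg
    else:
        bg_before = bg_after = 0.0
    total = bg_before + duration + bg_after
    T = int(round(total * fps))
    t = np.arange(T) / fps
    bg_angles, bg_root = _background_angles(t, rng, fps)
    ex_angles, ex_root = _program_angles(
        program, t - bg_before, params, rng, fps
    )
    t0, t1 = bg_before, bg_before + duration
    if background_fraction > 0:
        w = _blend_weight(t, t0, t1)
    else:
        w = np.ones_like(t)
    channels = {}
    for chan in bg_angles:
        ex = ex_angles.get(
            chan, np.full(T, BASE_POSTURE.get(chan, 0.0))
        )
        channels[chan] = w * ex + (1 - w) * bg_angles[chan]
    root_y = w * ex_root + (1 - w) * bg_root
    xyz = forward_kinematics(channels, root_y)
    if params.noise_sigma > 0:
        xyz = xyz + rng.normal(0.0, params.noise_sigma, xyz.shape)
    seq = SkeletonSequence(
        t,
        xyz,
        np.ones((T, N_JOINTS), dtype=bool),
        fps,
        subject_id=f"{program.name}_q{params.quality:g}",
    )
    labels = LabelTrack(
        [LabelSegment(round(t0, 6), round(t1, 6), program.class_id, params.quality)]
    )
    return DatasetItem(
        seq, labels, program.class_id, params.quality, params.speed, params.phase, params.seed
    )


def generate_dataset(
    n_classes: int = 9,
    n_per_class: int = 10,
    background_fraction: float = 0.3,
    seed: int = 0,
    fps: float = 30.0,
    duration: float = 60.0,
    qualities: tuple[float, ...] | None = None,
    programs: list[ExerciseProgram] | None = None,
    out_dir: str | Path | None = None,
    dialect: str = "wide-csv",
) -> list[DatasetItem]:
    """Generate a labeled multi-class dataset of exercise executions.

    One sequence per repetition: background wander, a ``duration``-second
    execution of the class program (smoothly blended in), background again,
    sized so exercise time is a ``1 - background_fraction`` share.  Each
    repetition draws its own speed and phase; qualities follow the coach
    ladder.  With ``out_dir`` set, sequences, label tracks and a JSON
    manifest are written to disk.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    programs = programs if programs is not None else DEFAULT_PROGRAMS
    if n_classes > len(programs):
        raise ValueError(f"only {len(programs)} programs available")
    qualities = qualities if qualities is not None else DEFAULT_QUALITY_LADDER
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_classes * n_per_class)
    items: list[DatasetItem] = []
    n = 0
    for program in programs[:n_classes]:
        for rep in range(n_per_class):
            child = children[n]
            n += 1
            rng = np.random.default_rng(child)
            params = ExecutionParams(
                speed=float(rng.uniform(0.85, 1.15)),
                phase=float(rng.uniform(0.0, 2 * np.pi)),
                quality=float(qualities[rep % len(qualities)]),
                seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
            )
            items.append(
                _make_item(program, params, duration, background_fraction, fps, rng)
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = "json" if dialect == "json" else "csv"
        manifest = {"fps": fps, "dialect": dialect, "items": []}
        for i, item in enumerate(items):
            seq_name = f"seq_{item.class_id:02d}_{i:03d}.{ext}"
            lab_name = f"labels_{item.class_id:02d}_{i:03d}.csv"
            write_sequence(item.sequence, out_dir / seq_name, dialect)
            write_labels(item.labels, out_dir / lab_name)
            manifest["items"].append(
                {
                    "sequence": seq_name,
                    "labels": lab_name,
                    "class_id": item.class_id,
                    "quality": item.quality,
                    "speed": item.speed,
                    "phase": item.phase,
                    "seed": item.seed,
                }
            )
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return items
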