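"""Reading, writing and validating 20-joint 3D skeleton sequences.

A skeleton sequence is the raw input of the pipeline: for every depth frame
the sensor SDK reports the 3D position (meters) of 20 named body joints,
some of which may be untracked ("invalid") in a given frame.  Three on-disk
dialects are supported:

``wide-csv``
    header ``time,j01_x,j01_y,j01_z,...,j20_z``, one row per frame; an empty
    cell marks the joint invalid in that frame.
``long-csv``
    header ``frame,time,joint_id,x,y,z,valid``, twenty rows per frame.
``json``
    ``{"fps": float, "joint_map": {...}, "frames": [{"t": float,
    "xyz": [[x,y,z] x20], "valid": [bool x20]}]}``.

Ground-truth annotations (exercise segments with optional coach scores) are
carried by :class:`LabelTrack` and stored as ``t_start,t_end,class_id,score``
CSV files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

N_JOINTS = 20

#: Canonical joint numbering (1-based).  The whole feature bank resolves its
#: node indices through this single table, so a different reading of the
#: sensor's joint layout requires editing only this file.
CANONICAL_JOINT_MAP: dict[int, str] = {
    1: "shoulder_right",
    2: "shoulder_left",
    3: "hip_left",
    4: "hip_right",
    5: "elbow_left",
    6: "elbow_right",
    7: "head",
    8: "ankle_left",
    9: "ankle_right",
    10: "knee_left",
    11: "knee_right",
    12: "shoulder_center",
    13: "wrist_left",
    14: "wrist_right",
    15: "hip_center",
    16: "spine",
    17: "hand_left",
    18: "hand_right",
    19: "foot_left",
    20: "foot_right",
}

JOINT_INDEX: dict[str, int] = {name: idx for idx, name in CANONICAL_JOINT_MAP.items()}

DIALECTS = ("wide-csv", "long-csv", "json")


class SkeletonFormatError(ValueError):
    """Malformed file or a frame violating the 20-joint schema."""


@dataclass(frozen=True)
class SkeletonFrame:
    """One time sample: 20 joint positions plus per-joint tracking validity."""

    time: float
    joints: np.ndarray  # (20, 3) float, meters; NaN where invalid
    validity: np.ndarray  # (20,) bool

    def __post_init__(self) -> None:
        if self.joints.shape != (N_JOINTS, 3):
            raise SkeletonFormatError(
                f"frame at t={self.time} has joint array {self.joints.shape}, "
                f"expected ({N_JOINTS}, 3)"
            )
        if self.validity.shape != (N_JOINTS,):
            raise SkeletonFormatError("validity must have one flag per joint")
        if not np.all(np.isfinite(self.joints[self.validity])):
            raise SkeletonFormatError(
                f"frame at t={self.time} has non-finite coordinates on valid joints"
            )


@dataclass
class SkeletonSequence:
    """A uniformly sampled sequence of skeleton frames.

    Times are seconds from sequence start and must advance by 1/fps within a
    1% tolerance.  Positions are stored as a ``(T, 20, 3)`` array with NaN at
    invalid cells.
    """

    times: np.ndarray  # (T,)
    xyz: np.ndarray  # (T, 20, 3)
    valid: np.ndarray  # (T, 20) bool
    fps: float
    subject_id: str = ""
    joint_map: dict[int, str] = field(default_factory=lambda: dict(CANONICAL_JOINT_MAP))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        T = len(self.times)
        if self.xyz.shape != (T, N_JOINTS, 3):
            raise SkeletonFormatError(
                f"positions have shape {self.xyz.shape}, expected ({T}, {N_JOINTS}, 3)"
            )
        if self.valid.shape != (T, N_JOINTS):
            raise SkeletonFormatError("validity mask shape mismatch")
        if T > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.any(np.abs(dts - 1.0 / self.fps) > 0.01 / self.fps):
                raise ValueError(
                    "frame spacing inconsistent with fps (>1% deviation)"
                )
        if not np.all(np.isfinite(self.xyz[self.valid])):
            raise SkeletonFormatError("non-finite coordinates on valid joints")
        if set(self.joint_map) != set(range(1, N_JOINTS + 1)):
            raise ValueError("joint_map must cover indices 1..20")
        if len(set(self.joint_map.values())) != N_JOINTS:
            raise ValueError("joint_map names must be unique")

    # -- basic accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Span covered by the sequence under the half-open convention."""
        return self.n_frames / self.fps

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(float(self.times[i]), self.xyz[i], self.valid[i])

    @property
    def frames(self) -> Iterator[SkeletonFrame]:
        return (self.frame(i) for i in range(self.n_frames))

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[SkeletonFrame],
        fps: float,
        subject_id: str = "",
        joint_map: dict[int, str] | None = None,
    ) -> "SkeletonSequence":
        times = np.array([f.time for f in frames])
        xyz = np.stack([f.joints for f in frames])
        valid = np.stack([f.validity for f in frames])
        return cls(times, xyz, valid, fps, subject_id, joint_map or dict(CANONICAL_JOINT_MAP))

    def decimate(self, target_fps: float) -> "SkeletonSequence":
        """Integer-stride frame decimation to approximately ``target_fps``.

        The stride is ``round(fps / target_fps)``; the effective rate of the
        returned sequence is ``fps / stride`` (e.g. 30 fps -> 4.3 fps uses
        stride 7, effective 4.286 fps).
        """
        stride = int(round(self.fps / target_fps))
        if stride < 1:
            raise ValueError("target_fps exceeds the native frame rate")
        if stride == 1:
            return self
        return SkeletonSequence(
            self.times[::stride],
            self.xyz[::stride],
            self.valid[::stride],
            self.fps / stride,
            self.subject_id,
            dict(self.joint_map),
        )


# ---------------------------------------------------------------------------
# gap repair


def repair_gaps(seq: SkeletonSequence, max_gap: int) -> SkeletonSequence:
    """Linearly interpolate short per-joint tracking dropouts.

    Runs of invalid frames of length <= ``max_gap`` that are flanked by valid
    positions on both sides are filled by linear interpolation in time and
    marked valid.  Longer runs, and runs touching either end of the sequence,
    are left untouched.  Valid samples are never altered.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    xyz = seq.xyz.copy()
    valid = seq.valid.copy()
    T = seq.n_frames
    for j in range(N_JOINTS):
        v = valid[:, j]
        i = 0
        while i < T:
            if v[i]:
                i += 1
                continue
            start = i
            while i < T and not v[i]:
                i += 1
            end = i  # run is [start, end)
            if start == 0 or end == T or (end - start) > max_gap:
                continue
            t0, t1 = seq.times[start - 1], seq.times[end]
            p0, p1 = xyz[start - 1, j], xyz[end, j]
            for k in range(start, end):
                w = (seq.times[k] - t0) / (t1 - t0)
                xyz[k, j] = (1 - w) * p0 + w * p1
            valid[start:end, j] = True
    return replace(seq, times=seq.times.copy(), xyz=xyz, valid=valid)


# ---------------------------------------------------------------------------
# readers / writers

_WIDE_COLUMNS = ["time"] + [
    f"j{j:02d}_{ax}" for j in range(1, N_JOINTS + 1) for ax in "xyz"
]


def _infer_fps(times: np.ndarray) -> float:
    if len(times) < 2:
        return 30.0
    return 1.0 / float(np.median(np.diff(times)))


def read_sequence(path: str | Path, dialect: str) -> SkeletonSequence:
    """Read a skeleton sequence in the named dialect.

    Missing joints are flagged invalid (NaN position), never silently zeroed.
    Raises :class:`SkeletonFormatError` on malformed input, naming the
    offending frame/line where possible.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    subject = path.stem
    if dialect == "wide-csv":
        df = pd.read_csv(path)
        if list(df.columns) != _WIDE_COLUMNS:
            raise SkeletonFormatError(
                f"{path}: wide-csv header mismatch "
                f"(got {len(df.columns)} columns, expected {len(_WIDE_COLUMNS)})"
            )
        times = df["time"].to_numpy(float)
        coords = df.iloc[:, 1:].to_numpy(float).reshape(len(df), N_JOINTS, 3)
        valid = ~np.isnan(coords).any(axis=2)
        return SkeletonSequence(times, coords, valid, _infer_fps(times), subject)
    if dialect == "long-csv":
        df = pd.read_csv(path)
        expected = ["frame", "time", "joint_id", "x", "y", "z", "valid"]
        if list(df.columns) != expected:
            raise SkeletonFormatError(f"{path}: long-csv header mismatch")
        frames = []
        times = []
        for fid, grp in df.groupby("frame", sort=True):
            ids = sorted(grp["joint_id"].tolist())
            if ids != list(range(1, N_JOINTS + 1)):
                raise SkeletonFormatError(
                    f"{path}: frame {fid} lists {len(grp)} joints "
                    f"(need exactly joint_id 1..{N_JOINTS})"
                )
            grp = grp.sort_values("joint_id")
            xyz = grp[["x", "y", "z"]].to_numpy(float)
            v = grp["valid"].to_numpy().astype(bool)
            xyz[~v] = np.nan
            t = float(grp["time"].iloc[0])
            frames.append((xyz, v))
            times.append(t)
        times = np.array(times)
        xyz = np.stack([f[0] for f in frames])
        valid = np.stack([f[1] for f in frames])
        return SkeletonSequence(times, xyz, valid, _infer_fps(times), subject)
    # json
    with open(path) as fh:
        try:
            blob = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SkeletonFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        fps = float(blob["fps"])
        raw_map = {int(k): str(v) for k, v in blob["joint_map"].items()}
        raw_frames = blob["frames"]
    except (KeyError, TypeError, ValueError) as exc:
        raise SkeletonFormatError(f"{path}: missing or malformed top-level field: {exc}") from exc
    times, xyzs, valids = [], [], []
    for i, fr in enumerate(raw_frames):
        xyz = np.asarray(fr["xyz"], dtype=float)
        if xyz.shape != (N_JOINTS, 3):
            raise SkeletonFormatError(
                f"{path}: frame {i} has {xyz.shape[0]} joints, expected {N_JOINTS}"
            )
        v = np.asarray(fr["valid"], dtype=bool)
        xyz = xyz.copy()
        xyz[~v] = np.nan
        times.append(float(fr["t"]))
        xyzs.append(xyz)
        valids.append(v)
    return SkeletonSequence(
        np.array(times), np.stack(xyzs), np.stack(valids), fps, subject, raw_map
    )


def write_sequence(seq: SkeletonSequence, path: str | Path, dialect: str) -> Path:
    """Write ``seq`` in the named dialect; round-trips to 1e-6 m."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "wide-csv":
        coords = seq.xyz.reshape(seq.n_frames, N_JOINTS * 3).copy()
        coords[np.repeat(~seq.valid, 3, axis=1)] = np.nan
        df = pd.DataFrame(coords, columns=_WIDE_COLUMNS[1:])
        df.insert(0, "time", seq.times)
        df.to_csv(path, index=False)
    elif dialect == "long-csv":
        rows = []
        for i in range(seq.n_frames):
            for j in range(N_JOINTS):
                ok = bool(seq.valid[i, j])
                x, y, z = (seq.xyz[i, j] if ok else (np.nan, np.nan, np.nan))
                rows.append((i, seq.times[i], j + 1, x, y, z, int(ok)))
        pd.DataFrame(
            rows, columns=["frame", "time", "joint_id", "x", "y", "z", "valid"]
        ).to_csv(path, index=False)
    else:
        blob = {
            "fps": seq.fps,
            "joint_map": {str(k): v for k, v in seq.joint_map.items()},
            "frames": [
                {
                    "t": float(seq.times[i]),
                    "xyz": [
                        [float(c) if np.isfinite(c) else None for c in seq.xyz[i, j]]
                        for j in range(N_JOINTS)
                    ],
                    "valid": [bool(b) for b in seq.valid[i]],
                }
                for i in range(seq.n_frames)
            ],
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)
    return path


# ---------------------------------------------------------------------------
# ground-truth label tracks


@dataclass(frozen=True)
class LabelSegment:
    t_start: float
    t_end: float
    class_id: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("segment must have t_start < t_end")
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0 (0 = unclassified)")
        if self.score is not None and not (0.0 <= self.score <= 100.0):
            raise ValueError("score must lie in [0, 100]")


@dataclass
class LabelTrack:
    """Non-overlapping labeled time segments; class 0 means unclassified."""

    segments: list[LabelSegment]

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.t_start)
        for a, b in zip(self.segments, self.segments[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValueError(
                    f"overlapping segments at t={b.t_start:.3f}"
                )

    def label_at(self, t: float) -> int:
        for s in self.segments:
            if s.t_start <= t < s.t_end:
                return s.class_id
        return 0

    def majority_label(self, t1: float, t2: float) -> int:
        """Ground-truth label of a window: the class covering the largest
        share of [t1, t2), with uncovered time counting toward class 0.
        Ties break toward the lower class id."""
        overlaps: dict[int, float] = {}
        covered = 0.0
        for s in self.segments:
            o = max(0.0, min(t2, s.t_end) - max(t1, s.t_start))
            if o > 0:
                overlaps[s.class_id] = overlaps.get(s.class_id, 0.0) + o
                covered += o
        overlaps[0] = overlaps.get(0, 0.0) + (t2 - t1) - covered
        best = min(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))
        return best[0]

    @property
    def span(self) -> tuple[float, float]:
        if not self.segments:
            return (0.0, 0.0)
        return (self.segments[0].t_start, self.segments[-1].t_end)


def read_labels(path: str | Path) -> LabelTrack:
    df = pd.read_csv(path)
    expected = ["t_start", "t_end", "class_id", "score"]
    if list(df.columns) != expected:
        raise SkeletonFormatError(f"{path}: labels header mismatch")
    segs = []
    for _, row in df.iterrows():
        score = None if pd.isna(row["score"]) else float(row["score"])
        segs.append(
            LabelSegment(float(row["t_start"]), float(row["t_end"]), int(row["class_id"]), score)
        )
    return LabelTrack(segs)


def write_labels(track: LabelTrack, path: str | Path) -> Path:
    df = pd.DataFrame(
        [(s.t_start, s.t_end, s.class_id, s.score) for s in track.segments],
        columns=["t_start", "t_end", "class_id", "score"],
    )
    df.to_csv(path, index=False)
    return Path(path)
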