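"""Instantaneous angular and NDDI features from skeleton frames.

Each frame yields 36 features: 26 joint angles (law of cosines at a vertex
joint, degrees in [0, 180]) and 10 Normalized Difference Distance Indices
(NDDI = (d1 - d2)/(d1 + d2) for two inter-joint distances, dimensionless in
[-1, 1]).  Both families are invariant to rigid motion and uniform scaling
of the skeleton, which is what makes the downstream descriptors robust to
sensor placement and body size.

The shipped bank (``data/feature_bank.csv``) lists the node tuples for all
36 features; nodes are resolved through
:data:`kinescore.skeleton.CANONICAL_JOINT_MAP`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .skeleton import N_JOINTS, SkeletonSequence

N_FEATURES = 36
_EPS = 1e-12


class WindowError(ValueError):
    """Window bounds invalid or too short for descriptor computation."""


@dataclass(frozen=True)
class FeatureSpec:
    """One row of the feature bank.

    ``nodes`` is ``(i, v, j)`` for an angular feature (``v`` the vertex) or
    ``(i, j, m, n)`` for an NDDI comparing d(i,j) against d(m,n).
    """

    feature_id: int
    kind: str  # "angular" | "nddi"
    nodes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("angular", "nddi"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        n_expected = 3 if self.kind == "angular" else 4
        if len(self.nodes) != n_expected:
            raise ValueError(
                f"feature {self.feature_id}: {self.kind} needs {n_expected} nodes"
            )
        for n in self.nodes:
            if not 1 <= n <= N_JOINTS:
                raise ValueError(f"feature {self.feature_id}: node {n} out of range")


def load_default_bank() -> list[FeatureSpec]:
    """Load the canonical 36-feature bank shipped with the package."""
    with resources.files("kinescore.data").joinpath("feature_bank.csv").open() as fh:
        df = pd.read_csv(fh)
    bank = []
    for _, row in df.iterrows():
        kind = row["kind"]
        if kind == "angular":
            nodes = (int(row["i"]), int(row["v"]), int(row["j"]))
        else:
            nodes = (int(row["i"]), int(row["j"]), int(row["m"]), int(row["n"]))
        bank.append(FeatureSpec(int(row["feature_id"]), kind, nodes))
    return bank


def bank_hash(bank: list[FeatureSpec]) -> str:
    """Stable digest of a bank; stored in model files for compatibility checks."""
    canon = ";".join(
        f"{s.feature_id}:{s.kind}:{','.join(map(str, s.nodes))}" for s in bank
    )
    return hashlib.sha256(canon.encode()).hexdigest()


_DEFAULT_BANK: list[FeatureSpec] | None = None


def default_bank() -> list[FeatureSpec]:
    global _DEFAULT_BANK
    if _DEFAULT_BANK is None:
        _DEFAULT_BANK = load_default_bank()
    return _DEFAULT_BANK


# ---------------------------------------------------------------------------
# scalar feature primitives


def angular_feature(p_i: np.ndarray, p_v: np.ndarray, p_j: np.ndarray) -> float:
    """Angle (degrees) at vertex ``p_v`` subtended by ``p_i`` and ``p_j``.

    Law of cosines on the triangle (i, v, j).  Returns NaN when either arm
    has zero length (degenerate vertex), which callers treat as an invalid
    sample rather than fabricated geometry.
    """
    a = float(np.linalg.norm(np.subtract(p_i, p_v)))
    b = float(np.linalg.norm(np.subtract(p_j, p_v)))
    if a <= _EPS or b <= _EPS:
        return float("nan")
    c = float(np.linalg.norm(np.subtract(p_i, p_j)))
    cosang = (a * a + b * b - c * c) / (2.0 * a * b)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def nddi_feature(
    p_i: np.ndarray, p_j: np.ndarray, p_m: np.ndarray, p_n: np.ndarray
) -> float:
    """Normalized Difference Distance Index (d(i,j) - d(m,n))/(d(i,j) + d(m,n)).

    Dimensionless in [-1, 1]; NaN when both distances vanish.
    """
    d1 = float(np.linalg.norm(np.subtract(p_i, p_j)))
    d2 = float(np.linalg.norm(np.subtract(p_m, p_n)))
    if d1 + d2 <= _EPS:
        return float("nan")
    return (d1 - d2) / (d1 + d2)


# ---------------------------------------------------------------------------
# matrix extraction


@dataclass
class FeatureMatrix:
    """36 feature streams over time.

    ``values`` is (36, T); ``valid_mask`` marks cells computable from tracked,
    non-degenerate joints.  Angular rows lie in [0, 180] degrees, NDDI rows in
    [-1, 1], wherever valid.
    """

    values: np.ndarray  # (36, T)
    valid_mask: np.ndarray  # (36, T) bool
    fps: float
    kinds: tuple[str, ...]  # per row
    feature_ids: tuple[int, ...]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


@dataclass
class FeatureWindow:
    """A half-open window [t1, t2) of a feature matrix, sampled at its fps."""

    values: np.ndarray  # (36, n)
    valid_mask: np.ndarray
    kinds: tuple[str, ...]
    t1: float
    t2: float
    fps: float

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def invalid_fractions(self) -> np.ndarray:
        return 1.0 - self.valid_mask.mean(axis=1)

    def usable(self, max_invalid_fraction: float = 0.1) -> bool:
        return bool(np.all(self.invalid_fractions <= max_invalid_fraction))


def extract_features(
    seq: SkeletonSequence, bank: list[FeatureSpec] | None = None
) -> FeatureMatrix:
    """Evaluate every bank feature on every frame of ``seq`` (vectorized).

    A cell is invalid iff any required joint is untracked in that frame or
    the geometry is degenerate (zero-length angle arm / both NDDI distances
    zero); invalidity never propagates beyond the affected cell.
    """
    bank = bank if bank is not None else default_bank()
    P = seq.xyz  # (T, 20, 3)
    V = seq.valid  # (T, 20)
    T = seq.n_frames
    values = np.full((len(bank), T), np.nan)
    valid = np.zeros((len(bank), T), dtype=bool)
    for row, spec in enumerate(bank):
        idx = tuple(n - 1 for n in spec.nodes)
        joints_ok = np.all(V[:, list(idx)], axis=1)
        if spec.kind == "angular":
            i, v, j = idx
            a = np.linalg.norm(P[:, i] - P[:, v], axis=1)
            b = np.linalg.norm(P[:, j] - P[:, v], axis=1)
            c = np.linalg.norm(P[:, i] - P[:, j], axis=1)
            ok = joints_ok & (a > _EPS) & (b > _EPS)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (a**2 + b**2 - c**2) / (2 * a * b)
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            values[row, ok] = ang[ok]
            valid[row] = ok
        else:
            i, j, m, n = idx
            d1 = np.linalg.norm(P[:, i] - P[:, j], axis=1)
            d2 = np.linalg.norm(P[:, m] - P[:, n], axis=1)
            ok = joints_ok & (d1 + d2 > _EPS)
            with np.errstate(invalid="ignore", divide="ignore"):
                nd = (d1 - d2) / (d1 + d2)
            values[row, ok] = nd[ok]
            valid[row] = ok
    return FeatureMatrix(
        values,
        valid,
        seq.fps,
        tuple(s.kind for s in bank),
        tuple(s.feature_id for s in bank),
    )


def window(fm: FeatureMatrix, t1: float, t2: float) -> FeatureWindow:
    """Slice the half-open window [t1, t2); contains floor((t2-t1)*fps) samples.

    Raises :class:`WindowError` for inverted bounds, windows extending past
    the sequence end, or windows shorter than 2 samples (pairwise descriptors
    are undefined there).
    """
    if t1 >= t2:
        raise WindowError(f"need t1 < t2, got [{t1}, {t2})")
    i1 = int(np.floor(t1 * fm.fps + 1e-9))
    n = int(np.floor((t2 - t1) * fm.fps + 1e-9))
    if n < 2:
        raise WindowError(f"window [{t1}, {t2}) holds {n} samples; need >= 2")
    if i1 < 0 or i1 + n > fm.n_frames:
        raise WindowError(
            f"window [{t1}, {t2}) exceeds the sequence span [0, {fm.duration})"
        )
    return FeatureWindow(
        fm.values[:, i1 : i1 + n],
        fm.valid_mask[:, i1 : i1 + n],
        fm.kinds,
        t1,
        t2,
        fm.fps,
    )
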