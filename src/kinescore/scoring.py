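"""Quality scoring by geometric interpolation in CC-descriptor space.

For each class the training data provide one perfect execution (coach score
100, CC vector ``b``) and one or more imperfect executions (scores below
100, vectors ``w_m``).  Each line b -> w_m is a degradation direction.  A
window to be scored (vector ``x``) picks the line with the smallest
perpendicular distance, projects onto it, and linearly interpolates the
coach scale along the projection:

    u = (w_m - b)/||w_m - b||,  d = (x - b) . u,  D = ||w_m - b||
    score = 100                          if d < 0   (beyond the perfect side)
          = max(0, 100 - (d/D)(100 - S)) otherwise  (S the line's coach score)

so the score is 100 at b, S at w_m, decays linearly past w_m and clamps at 0.
Only windows lying fully inside a single exercise segment carry a meaningful
CC signature; mixed windows are refused with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import N_PAIRS
from .labeling import ResponseTrack
from .model import ClassModel, ExerciseModel, ScoreReferenceData
from .skeleton import LabelTrack


@dataclass(frozen=True)
class ScoreReference:
    w: np.ndarray
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score < 100.0:
            raise ValueError("imperfect reference score must lie in [0, 100)")


@dataclass
class ScoreReferenceSet:
    """Perfect vector b plus at least one scored imperfect vector."""

    class_id: int
    b: np.ndarray
    imperfect: list[ScoreReference]

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if not self.imperfect:
            raise ValueError("need at least one imperfect reference")
        for m, ref in enumerate(self.imperfect, 1):
            if np.linalg.norm(ref.w - self.b) == 0.0:
                raise ValueError(
                    f"reference {m} coincides with the perfect vector"
                )

    @classmethod
    def from_model(cls, data: ScoreReferenceData, class_id: int) -> "ScoreReferenceSet":
        return cls(
            class_id,
            data.b,
            [ScoreReference(w, s) for w, s in data.imperfect],
        )

    def subset(self, n_imperfect: int) -> "ScoreReferenceSet":
        """Deterministic subset of ``n_imperfect`` references.

        The references are picked at evenly spaced positions of the
        score-sorted candidate list, anchored at the worst execution, so a
        growing reference set covers the coach-score range with the most
        even spread (mirrors collecting additional scored training samples
        across the quality range).
        """
        if not 1 <= n_imperfect <= len(self.imperfect):
            raise ValueError("n_imperfect out of range")
        pool = sorted(range(len(self.imperfect)), key=lambda m: self.imperfect[m].score)
        n = len(pool)
        if n_imperfect == n:
            chosen = sorted(pool)
        else:
            chosen = sorted(
                {pool[round(j * (n - 1) / n_imperfect)] for j in range(n_imperfect)}
            )
        return ScoreReferenceSet(
            self.class_id, self.b, [self.imperfect[m] for m in chosen]
        )


@dataclass(frozen=True)
class ScoreResult:
    score: float
    m_star: int  # 1-based index of the chosen reference line
    d: float  # signed projection length along the chosen line
    D: float  # length of the chosen line
    v: float  # perpendicular distance to the chosen line


def project_onto_reference(
    x: np.ndarray, b: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Signed projection d and perpendicular distance v of x onto line b->w."""
    x = np.asarray(x, float)
    b = np.asarray(b, float)
    w = np.asarray(w, float)
    axis = w - b
    length = float(np.linalg.norm(axis))
    if length == 0.0:
        raise ValueError("reference endpoints coincide")
    u = axis / length
    rel = x - b
    d = float(rel @ u)
    v = float(np.linalg.norm(rel - d * u))
    return d, v


def score_vector(x: np.ndarray, refs: ScoreReferenceSet) -> ScoreResult:
    """Score one CC descriptor vector against a class's reference geometry."""
    projections = [project_onto_reference(x, refs.b, ref.w) for ref in refs.imperfect]
    m_star = int(np.argmin([v for _, v in projections]))  # ties -> lowest m
    d, v = projections[m_star]
    ref = refs.imperfect[m_star]
    D = float(np.linalg.norm(ref.w - refs.b))
    if d < 0.0:
        s = 100.0
    else:
        s = max(0.0, 100.0 - (d / D) * (100.0 - ref.score))
    return ScoreResult(s, m_star + 1, d, D, v)


# ---------------------------------------------------------------------------
# track-level scoring


@dataclass(frozen=True)
class WindowScore:
    t1: float
    t2: float
    label: int
    score: float | None
    m_star: int | None
    d: float | None
    D: float | None
    v: float | None
    reason: str = ""


def _window_is_pure(truth: LabelTrack, t1: float, t2: float, label: int) -> bool:
    return any(
        s.class_id == label and s.t_start - 1e-9 <= t1 and t2 <= s.t_end + 1e-9
        for s in truth.segments
    )


def score_windows(
    model: ExerciseModel,
    track: ResponseTrack,
    cc_vectors: list[np.ndarray],
    truth: LabelTrack | None = None,
    n_imperfect: int | None = None,
) -> list[WindowScore]:
    """Score every labeled window of a track.

    ``cc_vectors`` holds the 630-component CC vector of each window, aligned
    with ``track.windows``.  Windows labeled 0 are skipped; when ``truth`` is
    given, only windows lying fully inside a single ground-truth segment of
    the predicted class are scored (mixed windows get a reason instead of a
    score).  ``n_imperfect`` restricts each class's reference set via
    :meth:`ScoreReferenceSet.subset`.
    """
    if len(cc_vectors) != len(track.windows):
        raise ValueError("one CC vector per window required")
    results: list[WindowScore] = []
    ref_cache: dict[int, ScoreReferenceSet | None] = {}
    for wlab, cc in zip(track.windows, cc_vectors):
        if wlab.final == 0:
            results.append(
                WindowScore(wlab.t1, wlab.t2, 0, None, None, None, None, None, "unclassified")
            )
            continue
        if truth is not None and not _window_is_pure(truth, wlab.t1, wlab.t2, wlab.final):
            results.append(
                WindowScore(
                    wlab.t1, wlab.t2, wlab.final, None, None, None, None, None, "mixed_window"
                )
            )
            continue
        cid = wlab.final
        if cid not in ref_cache:
            cls: ClassModel = model.class_model(cid)
            if cls.score_ref is None:
                ref_cache[cid] = None
            else:
                refs = ScoreReferenceSet.from_model(cls.score_ref, cid)
                if n_imperfect is not None:
                    refs = refs.subset(min(n_imperfect, len(refs.imperfect)))
                ref_cache[cid] = refs
        refs = ref_cache[cid]
        if refs is None:
            results.append(
                WindowScore(
                    wlab.t1, wlab.t2, cid, None, None, None, None, None, "scoring_disabled"
                )
            )
            continue
        res = score_vector(np.asarray(cc, float), refs)
        results.append(
            WindowScore(wlab.t1, wlab.t2, cid, res.score, res.m_star, res.d, res.D, res.v)
        )
    return results
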