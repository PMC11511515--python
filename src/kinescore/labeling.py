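"""Sliding-window labeling of skeleton sequences.

A window of length delta_t slides over the sequence in steps of dt.  For each
window the selected MI descriptors of every class are computed, each class's
adaptive CEM kernel (rebuilt against the elapsed-window background) produces
a response, and the class with the maximum response wins the *initial* label.
The label is kept only if a second, independent check passes: the Pearson
correlation between the window's full 630-component CC descriptor vector and
the winning class's training CC profile must exceed the confirmation
threshold (0.5 by default); otherwise the window is left unclassified
(label 0).  After labeling, the window's selected-descriptor vectors join
each class's background buffer, so the context only ever contains windows
strictly before the one under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptors as desc
from .cem import BackgroundBuffer, ClassTemplate, adaptive_covariance, cem_kernel
from .config import PipelineConfig
from .features import FeatureMatrix, FeatureSpec, WindowError, bank_hash, default_bank, extract_features, window
from .model import ExerciseModel
from .skeleton import SkeletonSequence


@dataclass(frozen=True)
class WindowLabel:
    t1: float
    t2: float
    responses: np.ndarray  # (n_T,) TR values, class order ascending
    initial: int  # argmax class id (0 only for unusable windows)
    confirm_r: float  # confirmation correlation (NaN if undefined)
    final: int  # 0 = unclassified
    reason: str = ""  # set when final == 0


@dataclass
class ResponseTrack:
    """Per-window responses and labels of one labeled sequence."""

    class_ids: list[int]
    windows: list[WindowLabel] = field(default_factory=list)

    def final_labels(self) -> np.ndarray:
        return np.array([w.final for w in self.windows], dtype=int)

    def window_bounds(self) -> list[tuple[float, float]]:
        return [(w.t1, w.t2) for w in self.windows]

    def segments(self) -> list[tuple[float, float, int]]:
        """Merge consecutive equal final labels into (t_start, t_end, label)."""
        segs: list[tuple[float, float, int]] = []
        for w in self.windows:
            if segs and segs[-1][2] == w.final and w.t1 <= segs[-1][1]:
                segs[-1] = (segs[-1][0], w.t2, w.final)
            else:
                segs.append((w.t1, w.t2, w.final))
        return segs

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "t_i": [w.t1 for w in self.windows],
            "t_j": [w.t2 for w in self.windows],
        }
        for n, cid in enumerate(self.class_ids):
            cols[f"TR_{cid}"] = [float(w.responses[n]) for w in self.windows]
        cols["initial"] = [w.initial for w in self.windows]
        cols["confirm_r"] = [w.confirm_r for w in self.windows]
        cols["final"] = [w.final for w in self.windows]
        cols["reason"] = [w.reason for w in self.windows]
        return pd.DataFrame(cols)

    def write_csv(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path, index=False)
        return Path(path)


def _confirmation(cc_vec: np.ndarray, cls, mode: str) -> float:
    """Pearson correlation against the class's training CC profile.

    ``mean`` correlates against the class mean vector; ``nearest`` takes the
    maximum correlation over the class's individual training samples.
    Undefined correlations (constant vectors) return -inf so confirmation
    fails cleanly.
    """

    def _r(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.sqrt((a**2).sum()), np.sqrt((b**2).sum())
        if na == 0.0 or nb == 0.0:
            return -np.inf
        return float(a @ b / (na * nb))

    if mode == "nearest":
        return max(_r(cc_vec, s) for s in cls.cc_samples)
    return _r(cc_vec, cls.cc_mean)


def classify_window(
    model: ExerciseModel,
    d_by_class: dict[int, np.ndarray],
    cc_vec: np.ndarray,
    buffers: dict[int, BackgroundBuffer],
    t1: float = 0.0,
    t2: float = 0.0,
) -> WindowLabel:
    """Core decision rule on precomputed descriptors (no feature extraction).

    Ties in the response argmax break toward the lowest class id.  The
    window's vectors are *not* appended to the buffers here; the caller does
    that after labeling.
    """
    cfg = model.config
    responses = np.empty(len(model.classes))
    for n, cls in enumerate(model.classes):
        template = ClassTemplate(cls.class_id, cls.indices, cls.tsd)
        R = adaptive_covariance(template, buffers.get(cls.class_id))
        kern = cem_kernel(template, R, cfg.ridge_cond, cfg.ridge_scale)
        responses[n] = kern.h @ d_by_class[cls.class_id]
    winner_pos = int(np.argmax(responses))  # first max -> lowest class id
    initial = model.classes[winner_pos].class_id
    r = _confirmation(cc_vec, model.classes[winner_pos], cfg.confirm_mode)
    if r > cfg.confirm_threshold:
        return WindowLabel(t1, t2, responses, initial, r, initial)
    return WindowLabel(t1, t2, responses, initial, r, 0, reason="confirmation_failed")


def label_window(
    model: ExerciseModel,
    fm: FeatureMatrix,
    t1: float,
    t2: float,
    buffers: dict[int, BackgroundBuffer],
    bank: list[FeatureSpec] | None = None,
    append_to_buffers: bool = True,
) -> WindowLabel:
    """Label one window of a feature matrix and update the background context."""
    model.check_bank(bank_hash(bank if bank is not None else default_bank()))
    cfg = model.config
    fw = window(fm, t1, t2)
    if not fw.usable(cfg.max_invalid_fraction):
        return WindowLabel(
            t1, t2, np.zeros(len(model.classes)), 0, np.nan, 0, reason="unusable_window"
        )
    codes = desc.quantize_window(fw)
    all_pairs = sorted({k for cls in model.classes for k in cls.indices})
    mi_vals = dict(
        zip(
            all_pairs,
            desc.mi_for_pairs(fw, np.array(all_pairs), codes, cfg.entropy_base),
        )
    )
    d_by_class = {
        cls.class_id: np.array([mi_vals[k] for k in cls.indices])
        for cls in model.classes
    }
    cc_vec = desc.cc_vector(fw)
    lab = classify_window(model, d_by_class, cc_vec, buffers, t1, t2)
    if append_to_buffers:
        for cls in model.classes:
            buffers[cls.class_id].append(d_by_class[cls.class_id])
    return lab


def make_buffers(model: ExerciseModel, maxlen: int | None = None) -> dict[int, BackgroundBuffer]:
    return {
        cls.class_id: BackgroundBuffer(len(cls.indices), maxlen)
        for cls in model.classes
    }


def label_sequence(
    model: ExerciseModel,
    seq: SkeletonSequence,
    delta_t: float | None = None,
    dt: float | None = None,
    buffers: dict[int, BackgroundBuffer] | None = None,
) -> ResponseTrack:
    """Slide a window over ``seq`` and label every position.

    The sequence is decimated to the model's analysis rate first.  Window
    positions are t = 0, dt, 2 dt, ... while t + delta_t <= duration.  The
    result is deterministic given (model, sequence, delta_t, dt, buffers).
    """
    cfg = model.config
    delta_t = cfg.delta_t if delta_t is None else delta_t
    dt = cfg.dt if dt is None else dt
    work = seq.decimate(cfg.fps) if seq.fps > cfg.fps * 1.01 else seq
    if delta_t < 2.0 / work.fps:
        raise ValueError("delta_t must cover at least two samples")
    if dt < 1.0 / work.fps - 1e-9:
        raise ValueError("dt must be at least one frame interval")
    if delta_t > work.duration + 1e-9:
        raise WindowError(
            f"window length {delta_t} s exceeds the sequence duration "
            f"{work.duration:.2f} s"
        )
    model.check_bank(bank_hash(default_bank()))
    fm = extract_features(work)
    if buffers is None:
        buffers = make_buffers(model)
    track = ResponseTrack(class_ids=model.class_ids)
    n_windows = int(np.floor((work.duration - delta_t) / dt + 1e-9)) + 1
    for w in range(n_windows):
        t1 = w * dt
        track.windows.append(
            label_window(
                model, fm, t1, t1 + delta_t, buffers,
                append_to_buffers=cfg.adaptive,
            )
        )
    return track


def read_track(path: str | Path) -> ResponseTrack:
    df = pd.read_csv(path)
    tr_cols = [c for c in df.columns if c.startswith("TR_")]
    class_ids = [int(c[3:]) for c in tr_cols]
    track = ResponseTrack(class_ids=class_ids)
    for _, row in df.iterrows():
        track.windows.append(
            WindowLabel(
                float(row["t_i"]),
                float(row["t_j"]),
                row[tr_cols].to_numpy(float),
                int(row["initial"]),
                float(row["confirm_r"]),
                int(row["final"]),
                "" if pd.isna(row.get("reason")) else str(row.get("reason")),
            )
        )
    return track
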