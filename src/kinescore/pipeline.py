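"""Training: from labeled sequences to a serialized detector/scoring model.

For every ground-truth exercise segment a training descriptor pair (MI, CC)
is computed on a window of the configured length centered in the segment,
at the configured analysis rate.  Per class the pipeline then selects the
n_D most discriminative MI components, assembles the CEM training matrices
and CC confirmation statistics, and -- when the class has a coach-scored
perfect execution and at least one imperfect one -- the scoring reference
geometry.  Training is deterministic; retraining on identical inputs yields
a byte-identical model file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np

from . import descriptors as desc
from .config import PipelineConfig
from .features import bank_hash, default_bank, extract_features, window
from .model import ClassModel, ExerciseModel, ScoreReferenceData
from .selection import TrainingPool, select_descriptors
from .skeleton import LabelTrack, SkeletonSequence, read_labels, read_sequence

logger = logging.getLogger("kinescore")


class LabeledItem(Protocol):
    sequence: SkeletonSequence
    labels: LabelTrack


@dataclass
class TrainingSample:
    class_id: int
    mi: np.ndarray  # (630,)
    cc: np.ndarray  # (630,)
    score: float | None


def _central_window(seg_start: float, seg_end: float, delta_t: float) -> tuple[float, float]:
    mid = 0.5 * (seg_start + seg_end)
    t1 = max(seg_start, mid - delta_t / 2)
    return t1, t1 + delta_t


def extract_training_samples(
    items: Iterable[LabeledItem], config: PipelineConfig
) -> list[TrainingSample]:
    """One (MI, CC) descriptor pair per ground-truth segment.

    MI vectors are computed on the ``delta_t`` stretch centered in the
    segment so their histogram-estimator bias matches what the labeling
    windows will see.  CC vectors are computed over the whole segment:
    correlation estimates carry no length bias, and the longer stretch
    sharpens the confirmation profiles and the scoring reference geometry.
    Segments shorter than ``delta_t`` are rejected.
    """
    samples: list[TrainingSample] = []
    for item in items:
        seq = item.sequence
        work = seq.decimate(config.fps) if seq.fps > config.fps * 1.01 else seq
        fm = extract_features(work)
        for seg in item.labels.segments:
            if seg.class_id == 0:
                continue
            if seg.t_end - seg.t_start < config.delta_t:
                raise ValueError(
                    f"training segment [{seg.t_start}, {seg.t_end}) shorter than "
                    f"the {config.delta_t} s descriptor window"
                )
            t1, t2 = _central_window(seg.t_start, seg.t_end, config.delta_t)
            fw = window(fm, t1, t2)
            mi, _cc = desc.descriptor_vectors(
                fw, config.entropy_base, config.max_invalid_fraction
            )
            seg_fw = window(fm, seg.t_start, min(seg.t_end, fm.duration))
            cc_full = desc.cc_vector(seg_fw)
            samples.append(TrainingSample(seg.class_id, mi.values, cc_full, seg.score))
    return samples


def build_pool(samples: list[TrainingSample]) -> TrainingPool:
    by_class_mi: dict[int, list[np.ndarray]] = {}
    by_class_cc: dict[int, list[np.ndarray]] = {}
    for s in samples:
        by_class_mi.setdefault(s.class_id, []).append(s.mi)
        by_class_cc.setdefault(s.class_id, []).append(s.cc)
    return TrainingPool(
        {c: np.vstack(v) for c, v in by_class_mi.items()},
        {c: np.vstack(v) for c, v in by_class_cc.items()},
    )


def _score_references(
    samples: list[TrainingSample], class_id: int
) -> ScoreReferenceData | None:
    own = [s for s in samples if s.class_id == class_id and s.score is not None]
    perfect = [s for s in own if s.score == 100.0]
    imperfect = [s for s in own if s.score < 100.0]
    if not perfect or not imperfect:
        logger.warning(
            "class %d: no perfect and/or imperfect scored execution; "
            "scoring disabled for this class",
            class_id,
        )
        return None
    # several perfect executions: their mean CC vector is the natural
    # representative of flawless form (and halves the endpoint noise)
    b = np.mean([s.cc for s in perfect], axis=0)
    return ScoreReferenceData(b, [(s.cc, float(s.score)) for s in imperfect])


def train(
    items: Iterable[LabeledItem],
    config: PipelineConfig | None = None,
    class_names: dict[int, str] | None = None,
) -> ExerciseModel:
    """Train detector kernels' ingredients and scoring references.

    Requires >= 2 training segments per class.  Classes without a perfect
    (score 100) and an imperfect (< 100) execution get labeling support but
    no scoring geometry (warning, not failure).
    """
    config = config if config is not None else PipelineConfig()
    samples = extract_training_samples(items, config)
    pool = build_pool(samples)
    class_models = []
    for cid in pool.class_ids:
        sel = select_descriptors(
            pool, cid, config.n_d, config.redundancy_filter, config.redundancy_corr
        )
        cols = [k - 1 for k in sel.indices]
        tsd = {c: pool.mi[c][:, cols] for c in pool.class_ids}
        cc_own = pool.cc[cid]
        class_models.append(
            ClassModel(
                class_id=cid,
                name=(class_names or {}).get(cid, f"class_{cid}"),
                indices=sel.indices,
                di_values=sel.di_values,
                tsd=tsd,
                cc_mean=cc_own.mean(axis=0),
                cc_samples=cc_own,
                score_ref=_score_references(samples, cid),
            )
        )
    return ExerciseModel(
        bank_hash=bank_hash(default_bank()),
        config=config,
        classes=class_models,
    )


# ---------------------------------------------------------------------------
# dataset directory loading (manifest written by synthetic.generate_dataset)


@dataclass
class LoadedItem:
    sequence: SkeletonSequence
    labels: LabelTrack
    class_id: int | None = None
    quality: float | None = None


def load_dataset(path: str | Path) -> list[LoadedItem]:
    """Load a dataset directory via its ``manifest.json``."""
    import json

    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    dialect = manifest.get("dialect", "wide-csv")
    items = []
    for entry in manifest["items"]:
        items.append(
            LoadedItem(
                read_sequence(path / entry["sequence"], dialect),
                read_labels(path / entry["labels"]),
                entry.get("class_id"),
                entry.get("quality"),
            )
        )
    return items
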