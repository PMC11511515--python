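"""Trained model container and its versioned JSON serialization.

A model file holds, per exercise class: the selected descriptor working set
K_q with DI values, the target signature g_q, the training matrix (all
classes' samples restricted to K_q) needed to rebuild adaptive CEM kernels,
the training CC statistics used for label confirmation, and the scoring
reference geometry (perfect + imperfect executions) when coach scores were
available.  Serialization is canonical (sorted keys, repr floats) so
retraining on identical inputs reproduces the file byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig

SCHEMA_VERSION = 1


class ModelCompatibilityError(RuntimeError):
    """Model applied under an incompatible feature bank or config."""


@dataclass
class ScoreReferenceData:
    """Serialized scoring geometry: perfect vector plus scored imperfect ones."""

    b: np.ndarray  # (630,) CC vector of the perfect execution
    imperfect: list[tuple[np.ndarray, float]]  # (w_m, S_wm < 100)


@dataclass
class ClassModel:
    class_id: int
    name: str
    indices: list[int]  # K_q
    di_values: list[float]
    tsd: dict[int, np.ndarray]  # class_id -> (n_i, n_D)
    cc_mean: np.ndarray  # (630,)
    cc_samples: np.ndarray  # (n_q, 630) own class's training CC vectors
    score_ref: ScoreReferenceData | None = None

    @property
    def g(self) -> np.ndarray:
        return self.tsd[self.class_id].mean(axis=0)


@dataclass
class ExerciseModel:
    bank_hash: str
    config: PipelineConfig
    classes: list[ClassModel]
    version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.classes = sorted(self.classes, key=lambda c: c.class_id)

    @property
    def class_ids(self) -> list[int]:
        return [c.class_id for c in self.classes]

    def class_model(self, class_id: int) -> ClassModel:
        for c in self.classes:
            if c.class_id == class_id:
                return c
        raise KeyError(class_id)

    def check_bank(self, bank_digest: str) -> None:
        if bank_digest != self.bank_hash:
            raise ModelCompatibilityError(
                "feature bank hash mismatch: the model was trained under a "
                "different feature bank"
            )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "bank_hash": self.bank_hash,
            "config": self.config.model_dump(),
            "classes": [
                {
                    "class_id": c.class_id,
                    "name": c.name,
                    "indices": list(map(int, c.indices)),
                    "di_values": [float(v) for v in c.di_values],
                    "tsd": {str(cid): arr.tolist() for cid, arr in sorted(c.tsd.items())},
                    "cc_mean": c.cc_mean.tolist(),
                    "cc_samples": c.cc_samples.tolist(),
                    "score_ref": None
                    if c.score_ref is None
                    else {
                        "b": c.score_ref.b.tolist(),
                        "imperfect": [
                            {"w": w.tolist(), "score": float(s)}
                            for w, s in c.score_ref.imperfect
                        ],
                    },
                }
                for c in self.classes
            ],
        }

    @classmethod
    def from_dict(cls, blob: dict) -> "ExerciseModel":
        if blob.get("version") != SCHEMA_VERSION:
            raise ModelCompatibilityError(
                f"unsupported model schema version {blob.get('version')}"
            )
        classes = []
        for c in blob["classes"]:
            ref = c.get("score_ref")
            classes.append(
                ClassModel(
                    class_id=int(c["class_id"]),
                    name=c["name"],
                    indices=[int(k) for k in c["indices"]],
                    di_values=[float(v) for v in c["di_values"]],
                    tsd={int(cid): np.asarray(a, float) for cid, a in c["tsd"].items()},
                    cc_mean=np.asarray(c["cc_mean"], float),
                    cc_samples=np.asarray(c["cc_samples"], float),
                    score_ref=None
                    if ref is None
                    else ScoreReferenceData(
                        np.asarray(ref["b"], float),
                        [
                            (np.asarray(e["w"], float), float(e["score"]))
                            for e in ref["imperfect"]
                        ],
                    ),
                )
            )
        return cls(
            bank_hash=blob["bank_hash"],
            config=PipelineConfig(**blob["config"]),
            classes=classes,
        )

    def save(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, separators=(",", ":"))
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "ExerciseModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
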