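"""Per-class ranking and selection of discriminative MI descriptors.

Each MI descriptor component k is scored for exercise class i by the
discrimination index

    DI(i, k) = |mean_in - mean_out| / (std_in + std_out)

where the "in" statistics run over class i's training descriptor vectors and
the "out" statistics over all other classes' vectors.  Large DI means the
component separates class i from the rest with tight spreads.  The top n_D
components by DI form the class's working set; an optional greedy redundancy
filter skips candidates whose training-pool values are near-duplicates
(|Pearson r| above a threshold) of an already selected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import N_PAIRS


@dataclass
class TrainingPool:
    """Per-class MI and CC descriptor vectors of the training samples."""

    mi: dict[int, np.ndarray]  # class_id -> (n_i, 630)
    cc: dict[int, np.ndarray]
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.mi) < 2:
            raise ValueError("need at least two classes")
        for cid, arr in self.mi.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != N_PAIRS:
                raise ValueError(f"class {cid}: MI pool must be (n, {N_PAIRS})")
            if arr.shape[0] < 2:
                raise ValueError(f"class {cid}: need >= 2 training samples")
            self.mi[cid] = arr
        for cid, arr in self.cc.items():
            self.cc[cid] = np.asarray(arr, dtype=float)

    @property
    def class_ids(self) -> list[int]:
        return sorted(self.mi)

    @property
    def n_classes(self) -> int:
        return len(self.mi)

    def stacked_mi(self) -> np.ndarray:
        """All training MI vectors, classes in ascending id order."""
        return np.vstack([self.mi[c] for c in self.class_ids])


@dataclass
class SelectedDescriptorSet:
    """Ordered working set K_q of pair indices for one class."""

    class_id: int
    indices: list[int]  # 1-based pair indices, selection order
    di_values: list[float]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selected indices must be unique")
        if len(self.indices) != len(self.di_values):
            raise ValueError("one DI value per selected index")


def di_profile(pool: TrainingPool, class_id: int) -> np.ndarray:
    """DI of every descriptor component for one class (length 630).

    Components where both group standard deviations vanish score +inf when
    the group means differ (perfectly separable, zero spread) and 0 when the
    means coincide.  Standard deviations use ddof=1.
    """
    if class_id not in pool.mi:
        raise ValueError(f"unknown class {class_id}")
    inside = pool.mi[class_id]
    outside = np.vstack([pool.mi[c] for c in pool.class_ids if c != class_id])
    if outside.shape[0] == 0:
        raise ValueError("complement pool is empty")
    num = np.abs(inside.mean(axis=0) - outside.mean(axis=0))
    den = inside.std(axis=0, ddof=1) + outside.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        di = num / den
    di[(den == 0) & (num > 0)] = np.inf
    di[num == 0] = 0.0
    return di


def discrimination_index(pool: TrainingPool, class_id: int, k: int) -> float:
    """DI of component ``k`` (1-based pair index) for ``class_id``."""
    if not 1 <= k <= N_PAIRS:
        raise ValueError(f"component index must lie in 1..{N_PAIRS}")
    return float(di_profile(pool, class_id)[k - 1])


def select_descriptors(
    pool: TrainingPool,
    class_id: int,
    n_d: int,
    redundancy_filter: bool = True,
    corr_threshold: float = 0.95,
) -> SelectedDescriptorSet:
    """Pick the class's n_D working descriptors by descending DI.

    Ties break toward the lower pair index, making selection deterministic.
    With the refinement filter on, the first pass keeps only candidates
    whose class mean lies *above* the complement mean (a usable detector
    signature) and skips candidates whose training-pool values correlate
    with an already-selected component beyond ``corr_threshold`` in absolute
    value; if fewer than n_D survive, deferred candidates backfill in DI
    order.
    """
    if not 1 <= n_d <= N_PAIRS:
        raise ValueError(f"n_d must lie in 1..{N_PAIRS}")
    di = di_profile(pool, class_id)
    order = np.lexsort((np.arange(N_PAIRS), -di))  # DI desc, index asc
    if not redundancy_filter:
        chosen = order[:n_d]
        return SelectedDescriptorSet(
            class_id, [int(k) + 1 for k in chosen], [float(di[k]) for k in chosen]
        )
    # Refinement pass.  Besides skipping near-duplicate columns, the first
    # pass defers components that are not *distinctively high* for the class
    # (its mean must exceed every training value observed outside the
    # class).  A component where the class sits low, or where another class
    # reaches target-level values, gives the downstream unit-gain detector a
    # weak or spoofable signature.  Deferred candidates backfill in DI order
    # if the distinctive pool runs out.
    inside = pool.mi[class_id]
    outside = np.vstack([pool.mi[c] for c in pool.class_ids if c != class_id])
    distinct_high = inside.mean(axis=0) > outside.max(axis=0)
    # Redundancy is judged on within-class-centered values: two components
    # are near-duplicates when their *fluctuations* co-move across training
    # samples (they measure the same underlying joint relationship), not
    # merely when they discriminate the same class.
    Xc = np.vstack(
        [pool.mi[c] - pool.mi[c].mean(axis=0) for c in pool.class_ids]
    )
    norms = np.sqrt((Xc**2).sum(axis=0))
    chosen: list[int] = []
    skipped: list[int] = []
    for k0 in order:
        if len(chosen) == n_d:
            break
        if not distinct_high[k0]:
            skipped.append(int(k0))
            continue
        redundant = False
        for s0 in chosen:
            if norms[k0] == 0 or norms[s0] == 0:
                continue  # constant column: no correlation evidence
            r = float(Xc[:, k0] @ Xc[:, s0] / (norms[k0] * norms[s0]))
            if abs(r) > corr_threshold:
                redundant = True
                break
        if redundant:
            skipped.append(int(k0))
        else:
            chosen.append(int(k0))
    for k0 in skipped:  # backfill to reach n_d
        if len(chosen) == n_d:
            break
        chosen.append(k0)
    return SelectedDescriptorSet(
        class_id, [k + 1 for k in chosen], [float(di[k]) for k in chosen]
    )
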