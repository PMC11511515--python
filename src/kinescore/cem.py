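"""Adaptive Constrained Energy Minimization detectors.

CEM treats each exercise class q as a "target" with signature g_q (the mean
of the class's training samples in its selected-descriptor space) and builds
the linear kernel

    H_q = R_q^-1 g_q / (g_q^T R_q^-1 g_q)

which responds with exactly 1 to the signature (unit-gain constraint) while
minimizing the mean squared response over the background described by the
correlation matrix R_q.  Here R_q blends two terms:

* a training term -- the class-balanced mean outer product of *all* classes'
  training samples restricted to K_q, and
* an adaptive term -- the mean outer product over the sliding windows of the
  sequence under test that have already elapsed (the background context),
  zero while no window has elapsed.

A small ridge is added only when R_q is numerically ill-conditioned.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ClassTemplate:
    """Target signature and training matrix of one class in K_q space."""

    class_id: int
    indices: list[int]  # K_q, 1-based pair indices
    tsd: dict[int, np.ndarray]  # class_id -> (n_i, n_D): all classes, K_q columns

    def __post_init__(self) -> None:
        n_d = len(self.indices)
        for cid, arr in self.tsd.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != n_d:
                raise ValueError(f"TSD block for class {cid} must be (n, {n_d})")
            self.tsd[cid] = arr
        if self.class_id not in self.tsd:
            raise ValueError("template must include its own class's samples")

    @property
    def n_d(self) -> int:
        return len(self.indices)

    @property
    def g(self) -> np.ndarray:
        """Representative vector: mean of the class's own training samples."""
        return self.tsd[self.class_id].mean(axis=0)

    @property
    def n_samples(self) -> int:
        return int(self.tsd[self.class_id].shape[0])


class BackgroundBuffer:
    """Selected-descriptor vectors of the elapsed windows of one sequence.

    Only windows strictly before the window under test may be present: the
    labeler appends each window's vector *after* labeling it.  A ``maxlen``
    capacity keeps a rolling context; the default is unbounded.
    """

    def __init__(self, n_d: int, maxlen: int | None = None):
        self.n_d = n_d
        self._vectors: deque[np.ndarray] = deque(maxlen=maxlen)
        self._sum = np.zeros((n_d, n_d))

    def __len__(self) -> int:
        return len(self._vectors)

    def append(self, d: np.ndarray) -> None:
        d = np.asarray(d, dtype=float)
        if d.shape != (self.n_d,):
            raise ValueError(f"expected vector of length {self.n_d}")
        if self._vectors.maxlen is not None and len(self._vectors) == self._vectors.maxlen:
            old = self._vectors[0]
            self._sum -= np.outer(old, old)
        self._vectors.append(d)
        self._sum += np.outer(d, d)

    def mean_outer(self) -> np.ndarray:
        """Time-averaged outer product over buffered windows; 0 when empty."""
        if not self._vectors:
            return np.zeros((self.n_d, self.n_d))
        return self._sum / len(self._vectors)


@dataclass
class CemKernel:
    """A trained detector kernel with its conditioning diagnostics."""

    h: np.ndarray
    condition_number: float
    ridge: float = 0.0

    @property
    def n_d(self) -> int:
        return self.h.shape[0]


def adaptive_covariance(
    template: ClassTemplate, buffer: BackgroundBuffer | None = None
) -> np.ndarray:
    """Background correlation matrix R_q: training term plus elapsed-window term.

    Training term: classes weighted equally (1/n_T), samples within a class
    equally (1/n_i).  Elapsed term: mean outer product over the buffer (the
    discrete form of a time-averaged integral over the elapsed sequence);
    zero for an empty or absent buffer.
    """
    n_d = template.n_d
    R = np.zeros((n_d, n_d))
    n_t = len(template.tsd)
    for arr in template.tsd.values():
        R += (arr.T @ arr) / arr.shape[0]
    R /= n_t
    if buffer is not None:
        if buffer.n_d != n_d:
            raise ValueError("buffer dimensionality does not match the template")
        R = R + buffer.mean_outer()
    return R


def cem_kernel(
    template: ClassTemplate,
    R: np.ndarray,
    ridge_cond: float = 1e10,
    ridge_scale: float = 1e-6,
) -> CemKernel:
    """Closed-form CEM kernel H = R^-1 g / (g^T R^-1 g).

    When cond(R) exceeds ``ridge_cond`` (or is non-finite), a ridge
    ``ridge_scale * trace(R)/n_D * I`` is added first.  A zero signature has
    no meaningful unit-gain constraint and raises.
    """
    g = template.g
    if not np.any(g):
        raise ValueError(f"class {template.class_id}: degenerate (zero) signature")
    R = np.asarray(R, dtype=float)
    cond = float(np.linalg.cond(R))
    ridge = 0.0
    if not np.isfinite(cond) or cond > ridge_cond:
        ridge = ridge_scale * float(np.trace(R)) / template.n_d
        if ridge <= 0.0:
            ridge = ridge_scale
        R = R + ridge * np.eye(template.n_d)
        cond = float(np.linalg.cond(R))
    rinv_g = np.linalg.solve(R, g)
    denom = float(g @ rinv_g)
    if not np.isfinite(denom) or denom <= 0.0:
        raise ValueError(
            f"class {template.class_id}: R is not positive definite on g"
        )
    return CemKernel(rinv_g / denom, cond, ridge)


def detector_response(kernel: CemKernel | np.ndarray, d: np.ndarray) -> float:
    """Detector response: dot product of the kernel with a descriptor vector."""
    h = kernel.h if isinstance(kernel, CemKernel) else np.asarray(kernel, float)
    d = np.asarray(d, dtype=float)
    if h.shape != d.shape:
        raise ValueError(f"dimension mismatch: kernel {h.shape}, vector {d.shape}")
    return float(h @ d)
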