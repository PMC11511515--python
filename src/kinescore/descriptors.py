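"""Pairwise mutual-information and correlation descriptors of a window.

For a window of the 36 feature streams, every unordered feature pair
(C(36,2) = 630 pairs) is summarized by two numbers:

* ``CC`` -- the Pearson correlation of the two streams (linear dependence),
* ``MI`` -- the mutual information of the two streams after quantizing each
  onto its feature family's fixed grid (18 ten-degree bins for angles, 20
  bins of width 0.1 for NDDIs): ``MI = H(Fi) + H(Fj) - H(Fi, Fj)`` on the
  joint histogram, in bits by default.

Because MI is computed from the histogram of samples it is blind to sample
order, which makes the MI descriptor vector insensitive to phase shifts and
moderate speed changes of a periodic motion -- the property the whole
labeling approach relies on.

Pair ``k`` (1..630) maps to the lexicographically ``k``-th pair
(1,2), (1,3), ..., (35,36) of feature ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import N_FEATURES, FeatureWindow

N_PAIRS = N_FEATURES * (N_FEATURES - 1) // 2  # 630

#: 0-based feature indices of pair k-1, lexicographic order.
PAIR_I, PAIR_J = np.triu_indices(N_FEATURES, k=1)

#: quantization grids per feature family: (lo, hi, n_bins)
QUANT_GRIDS: dict[str, tuple[float, float, int]] = {
    "angular": (0.0, 180.0, 18),
    "nddi": (-1.0, 1.0, 20),
}

_EDGE_EPS = 1e-9

#: Effective-constancy floor for CC streams, per feature family: a stream
#: whose sample standard deviation stays below half a quantization bin
#: varies below the method's own resolution (and below typical skeleton
#: jitter), so it takes the constant-stream convention (CC = 0).
CC_NOISE_FLOOR: dict[str, float] = {
    "angular": 0.5 * (QUANT_GRIDS["angular"][1] - QUANT_GRIDS["angular"][0]) / QUANT_GRIDS["angular"][2],
    "nddi": 0.5 * (QUANT_GRIDS["nddi"][1] - QUANT_GRIDS["nddi"][0]) / QUANT_GRIDS["nddi"][2],
}


class WindowUnusableError(ValueError):
    """Too many invalid cells in a window for reliable descriptors."""


def pair_to_index(i: int, j: int) -> int:
    """1-based pair index k of feature pair (i, j), 1 <= i < j <= 36."""
    if not (1 <= i < j <= N_FEATURES):
        raise ValueError(f"need 1 <= i < j <= {N_FEATURES}, got ({i}, {j})")
    i0, j0 = i - 1, j - 1
    return i0 * (2 * N_FEATURES - i0 - 1) // 2 + (j0 - i0)


def index_to_pair(k: int) -> tuple[int, int]:
    """Feature pair (i, j), 1-based, of pair index k in 1..630."""
    if not 1 <= k <= N_PAIRS:
        raise ValueError(f"pair index must lie in 1..{N_PAIRS}")
    return int(PAIR_I[k - 1]) + 1, int(PAIR_J[k - 1]) + 1


def quantize(values: np.ndarray, kind: str, n_bins: int | None = None) -> np.ndarray:
    """Map values onto the family's fixed grid; returns 1-based bin labels.

    Bins are left-closed/right-open except the final bin, which is closed so
    the range endpoints (180 degrees, NDDI = 1) fall into the last bin.
    Values outside the family's known range raise (an upstream invariant has
    been broken).
    """
    lo, hi, nb = QUANT_GRIDS[kind]
    if n_bins is not None:
        nb = n_bins
    v = np.asarray(values, dtype=float)
    if np.any(v < lo - _EDGE_EPS) or np.any(v > hi + _EDGE_EPS):
        bad = v[(v < lo - _EDGE_EPS) | (v > hi + _EDGE_EPS)][0]
        raise ValueError(f"{kind} value {bad} outside known range [{lo}, {hi}]")
    width = (hi - lo) / nb
    codes = np.floor((v - lo) / width).astype(np.int64) + 1
    return np.clip(codes, 1, nb)


def entropy_bits(codes: np.ndarray, n_bins: int, base: float = 2.0) -> float:
    """Plug-in entropy of 1-based bin labels; empty bins contribute zero."""
    counts = np.bincount(codes, minlength=n_bins + 1)[1:]
    p = counts[counts > 0] / codes.size
    return float(-(p * (np.log(p) / np.log(base))).sum())


def cc_descriptor(Fi: np.ndarray, Fj: np.ndarray) -> float:
    """Pearson correlation of two feature streams; 0.0 if either is constant.

    A constant stream carries no evidence of linear relation, so by
    convention its correlations are reported as 0 (keeping the descriptor
    vector complete and bounded) rather than undefined.
    """
    Fi = np.asarray(Fi, dtype=float)
    Fj = np.asarray(Fj, dtype=float)
    if Fi.shape != Fj.shape or Fi.size < 2:
        raise ValueError("streams must share a length >= 2")
    xi = Fi - Fi.mean()
    xj = Fj - Fj.mean()
    si = np.sqrt((xi**2).sum())
    sj = np.sqrt((xj**2).sum())
    if si == 0.0 or sj == 0.0:
        return 0.0
    return float(np.clip((xi * xj).sum() / (si * sj), -1.0, 1.0))


def is_constant(F: np.ndarray) -> bool:
    F = np.asarray(F)
    return bool(np.all(F == F.flat[0]))


def mi_descriptor(
    Fi: np.ndarray,
    Fj: np.ndarray,
    kinds: tuple[str, str] = ("angular", "angular"),
    base: float = 2.0,
) -> float:
    """Mutual information (bits) of two streams on the quantized joint grid."""
    Fi = np.asarray(Fi, dtype=float)
    Fj = np.asarray(Fj, dtype=float)
    if Fi.shape != Fj.shape or Fi.size < 2:
        raise ValueError("streams must share a length >= 2")
    ci = quantize(Fi, kinds[0])
    cj = quantize(Fj, kinds[1])
    nbi = QUANT_GRIDS[kinds[0]][2]
    nbj = QUANT_GRIDS[kinds[1]][2]
    return _mi_from_codes(ci, cj, nbi, nbj, base)


def _mi_from_codes(
    ci: np.ndarray, cj: np.ndarray, nbi: int, nbj: int, base: float = 2.0
) -> float:
    hi = entropy_bits(ci, nbi, base)
    hj = entropy_bits(cj, nbj, base)
    joint = (ci - 1) * nbj + (cj - 1)
    counts = np.bincount(joint, minlength=nbi * nbj)
    p = counts[counts > 0] / ci.size
    hij = float(-(p * (np.log(p) / np.log(base))).sum())
    return max(hi + hj - hij, 0.0)


# ---------------------------------------------------------------------------
# full descriptor vectors


@dataclass
class DescriptorVector:
    """630 pairwise descriptors of one window, in pair-index order."""

    kind: str  # "MI" | "CC"
    values: np.ndarray  # (630,)
    window: tuple[float, float]
    source_id: str = ""
    constant_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("MI", "CC"):
            raise ValueError("kind must be 'MI' or 'CC'")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PAIRS,):
            raise ValueError(f"descriptor vector must have {N_PAIRS} components")


def quantize_window(fw: FeatureWindow) -> np.ndarray:
    """Quantize all rows of a window onto their family grids (1-based codes).

    Invalid cells receive code 0 and must be masked out by the caller.
    """
    codes = np.zeros(fw.values.shape, dtype=np.int64)
    for r, kind in enumerate(fw.kinds):
        m = fw.valid_mask[r]
        if m.any():
            codes[r, m] = quantize(fw.values[r, m], kind)
    return codes


def descriptor_vectors(
    fw: FeatureWindow,
    base: float = 2.0,
    max_invalid_fraction: float = 0.1,
    source_id: str = "",
) -> tuple[DescriptorVector, DescriptorVector]:
    """Compute the (MI, CC) descriptor pair for one window.

    Raises :class:`WindowUnusableError` if any feature row has more than
    ``max_invalid_fraction`` invalid cells; below that threshold, invalid
    cells are dropped pairwise per descriptor.
    """
    if not fw.usable(max_invalid_fraction):
        worst = int(np.argmax(fw.invalid_fractions))
        raise WindowUnusableError(
            f"window [{fw.t1}, {fw.t2}) has {fw.invalid_fractions[worst]:.0%} "
            f"invalid cells in feature row {worst + 1}"
        )
    codes = quantize_window(fw)
    all_valid = bool(fw.valid_mask.all())
    mi = np.empty(N_PAIRS)
    cc = np.empty(N_PAIRS)
    eff_const = effective_constant_mask(fw)
    const = np.zeros(N_PAIRS, dtype=bool)
    vals = fw.values
    for k0 in range(N_PAIRS):
        i, j = PAIR_I[k0], PAIR_J[k0]
        if all_valid:
            ci, cj = codes[i], codes[j]
            Fi, Fj = vals[i], vals[j]
        else:
            m = fw.valid_mask[i] & fw.valid_mask[j]
            if m.sum() < 2:
                raise WindowUnusableError(
                    f"pair ({i + 1}, {j + 1}) has fewer than 2 jointly valid samples"
                )
            ci, cj = codes[i, m], codes[j, m]
            Fi, Fj = vals[i, m], vals[j, m]
        nbi = QUANT_GRIDS[fw.kinds[i]][2]
        nbj = QUANT_GRIDS[fw.kinds[j]][2]
        mi[k0] = _mi_from_codes(ci, cj, nbi, nbj, base)
        const[k0] = bool(eff_const[i] or eff_const[j])
        cc[k0] = 0.0 if const[k0] else cc_descriptor(Fi, Fj)
    win = (fw.t1, fw.t2)
    return (
        DescriptorVector("MI", mi, win, source_id),
        DescriptorVector("CC", cc, win, source_id, constant_mask=const),
    )


def mi_for_pairs(
    fw: FeatureWindow,
    pair_indices: np.ndarray,
    codes: np.ndarray | None = None,
    base: float = 2.0,
) -> np.ndarray:
    """MI values for a subset of 1-based pair indices (labeling fast path)."""
    if codes is None:
        codes = quantize_window(fw)
    out = np.empty(len(pair_indices))
    for n, k in enumerate(pair_indices):
        i, j = PAIR_I[k - 1], PAIR_J[k - 1]
        m = fw.valid_mask[i] & fw.valid_mask[j]
        ci, cj = codes[i, m], codes[j, m]
        nbi = QUANT_GRIDS[fw.kinds[i]][2]
        nbj = QUANT_GRIDS[fw.kinds[j]][2]
        out[n] = _mi_from_codes(ci, cj, nbi, nbj, base)
    return out


def effective_constant_mask(fw: FeatureWindow) -> np.ndarray:
    """Per-feature flag: stream variation below the family's noise floor."""
    flags = np.zeros(N_FEATURES, dtype=bool)
    for r, kind in enumerate(fw.kinds):
        m = fw.valid_mask[r]
        if not m.any():
            flags[r] = True
            continue
        flags[r] = float(fw.values[r, m].std()) < CC_NOISE_FLOOR[kind]
    return flags


def cc_vector(fw: FeatureWindow) -> np.ndarray:
    """Full 630-component CC vector of a window.

    Streams that are constant -- exactly, or effectively (variation below
    the family's noise floor, where any apparent correlation reflects
    shared-joint sensor jitter rather than motion) -- contribute 0.
    """
    const = effective_constant_mask(fw)
    pair_const = const[PAIR_I] | const[PAIR_J]
    if fw.valid_mask.all():
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(fw.values)
        C = np.nan_to_num(C, nan=0.0)
        out = np.clip(C[PAIR_I, PAIR_J], -1.0, 1.0)
    else:
        out = np.empty(N_PAIRS)
        for k0 in range(N_PAIRS):
            i, j = PAIR_I[k0], PAIR_J[k0]
            m = fw.valid_mask[i] & fw.valid_mask[j]
            out[k0] = cc_descriptor(fw.values[i, m], fw.values[j, m])
    out[pair_const] = 0.0
    return out


# ---------------------------------------------------------------------------
# CSV caching of descriptor vectors


def write_descriptors(vectors: list[DescriptorVector], path: str | Path) -> Path:
    rows = []
    for dv in vectors:
        rows.append([dv.kind, dv.window[0], dv.window[1], *dv.values])
    cols = ["kind", "t1", "t2"] + [f"v{k}" for k in range(1, N_PAIRS + 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return Path(path)


def read_descriptors(path: str | Path) -> list[DescriptorVector]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            DescriptorVector(
                row["kind"],
                row.iloc[3:].to_numpy(float),
                (float(row["t1"]), float(row["t2"])),
            )
        )
    return out
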