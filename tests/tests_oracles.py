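"""Independent reference implementations used by the test suite only."""

import numpy as np

from kinescore import descriptors as desc


def brute_force_mi(fi, fj, kind_i, kind_j, base=2.0):
    """Mutual information by explicit double-loop joint-histogram entropy."""
    ci = desc.quantize(fi, kind_i)
    cj = desc.quantize(fj, kind_j)
    nbi = desc.QUANT_GRIDS[kind_i][2]
    nbj = desc.QUANT_GRIDS[kind_j][2]
    n = len(ci)

    def H(counts):
        h = 0.0
        for c in counts:
            if c > 0:
                p = c / n
                h -= p * np.log(p) / np.log(base)
        return h

    hi = H([int((ci == b).sum()) for b in range(1, nbi + 1)])
    hj = H([int((cj == b).sum()) for b in range(1, nbj + 1)])
    joint = []
    for bi in range(1, nbi + 1):
        for bj in range(1, nbj + 1):
            joint.append(int(((ci == bi) & (cj == bj)).sum()))
    return hi + hj - H(joint)
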