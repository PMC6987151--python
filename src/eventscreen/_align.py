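"""Affine-gap Smith-Waterman kernels (numba-compiled).

Gap model: a gap of length k costs ``gap_open + k * gap_extend``, i.e.
the first gapped residue pays both the opening and the extension penalty.
Scores are integers in matrix units.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**9))


@njit(cache=False)
def sw_fill(a, b, mat, gap_open, gap_extend):  # pragma: no cover - exercised via wrappers
    """Full H/E/F dynamic-programming matrices for traceback."""
    m, n = a.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open - gap_extend
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_extend
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=False)
def sw_score(a, b, mat, gap_open, gap_extend):  # pragma: no cover
    """Best local alignment score only (two-row, for shuffle calibration)."""
    m, n = a.shape[0], b.shape[0]
    prev_h = np.zeros(n + 1, np.int32)
    prev_f = np.full(n + 1, NEG, np.int32)
    best = np.int32(0)
    for i in range(1, m + 1):
        cur_h = np.zeros(n + 1, np.int32)
        cur_f = np.empty(n + 1, np.int32)
        cur_f[0] = NEG
        e = NEG
        for j in range(1, n + 1):
            eo = cur_h[j - 1] - gap_open - gap_extend
            ee = e - gap_extend
            e = eo if eo > ee else ee
            fo = prev_h[j] - gap_open - gap_extend
            fe = prev_f[j] - gap_extend
            f = fo if fo > fe else fe
            cur_f[j] = f
            h = prev_h[j - 1] + mat[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            cur_h[j] = h
            if h > best:
                best = h
        prev_h = cur_h
        prev_f = cur_f
    return best
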