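"""Numba kernels for the banded affine-gap local alignment fill.

The band is expressed in diagonal coordinates: cell (i, b) corresponds to
query prefix length i (1..m) and window column j = i + d0 + b - bw
(1..nw), with b in [0, 2*bw].  Gap of length L costs open + L * ext.
Cells whose j falls outside the window are held at NEG and can neither
start nor relay an alignment.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(2 ** 29))


@njit(cache=True)
def banded_sw_fill(q, w, wmask, d0, bw, match, mismatch, gopen, gext):
    """Fill the banded Smith-Waterman matrices.

    q: query codes (0..3, 4 = N); w: window codes (0..3); wmask: bool,
    window positions whose base was an ambiguity code (forced mismatch).
    Returns (H, F, E, best_i, best_b, best_score); H/F/E have shape
    (m + 1, 2*bw + 1).  F is the vertical state (gap in reference,
    consumes query, CIGAR 'I'); E the horizontal state (gap in query,
    consumes reference, CIGAR 'D').
    """
    m = q.shape[0]
    nw = w.shape[0]
    width = 2 * bw + 1
    H = np.full((m + 1, width), NEG, dtype=np.int32)
    F = np.full((m + 1, width), NEG, dtype=np.int32)
    E = np.full((m + 1, width), NEG, dtype=np.int32)
    # row 0: empty query prefix; valid cells start at 0 (local alignment)
    for b in range(width):
        j = 0 + d0 + b - bw
        if 0 <= j <= nw:
            H[0, b] = 0
    best_i = 0
    best_b = 0
    best = np.int32(0)
    for i in range(1, m + 1):
        qc = q[i - 1]
        for b in range(width):
            j = i + d0 + b - bw
            if j < 1 or j > nw:
                continue
            # vertical (I): from row i-1, band offset b+1
            f = NEG
            if b + 1 < width:
                hup = H[i - 1, b + 1]
                fup = F[i - 1, b + 1]
                if hup > NEG:
                    f = hup - gopen - gext
                if fup > NEG and fup - gext > f:
                    f = fup - gext
            # horizontal (D): from same row, band offset b-1
            e = NEG
            if b - 1 >= 0 and j - 1 >= 1:
                hl = H[i, b - 1]
                el = E[i, b - 1]
                if hl > NEG:
                    e = hl - gopen - gext
                if el > NEG and el - gext > e:
                    e = el - gext
            # diagonal
            h = NEG
            hd = H[i - 1, b]
            if hd > NEG:
                wc = w[j - 1]
                if qc == wc and qc < 4 and not wmask[j - 1]:
                    h = hd + match
                else:
                    h = hd - mismatch
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, b] = h
            F[i, b] = f
            E[i, b] = e
            if h > best:
                best = h
                best_i = i
                best_b = b
    return H, F, E, best_i, best_b, best
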