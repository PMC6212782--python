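"""Affine-gap semiglobal dynamic-programming kernel.

Free end gaps on the reference only: the read is consumed in full, while
unaligned reference overhangs on either side cost nothing.  A gap of length
L costs ``gap_open + gap_extend * L``.  ``N`` (code 4) never matches.

The fill is numba-compiled; traceback is done by the caller from the
returned pointer matrices.  State codes: 0 = diagonal (match/mismatch),
1 = insertion (consumes read), 2 = deletion (consumes reference).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2**30)


@njit(cache=True)
def fill_matrices(read, ref, match, mismatch, gap_open, gap_extend):
    m = read.shape[0]
    n = ref.shape[0]
    M = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    X = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    Y = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    pM = np.zeros((m + 1, n + 1), dtype=np.int8)
    pX = np.zeros((m + 1, n + 1), dtype=np.int8)
    pY = np.zeros((m + 1, n + 1), dtype=np.int8)

    # Row 0: skipping any reference prefix is free (Y doubles as the start
    # state so the traceback can stop as soon as the read is exhausted).
    for j in range(n + 1):
        Y[0, j] = 0
        pY[0, j] = 2

    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        if i == 1:
            X[i, 0] = -open_cost
            pX[i, 0] = 2
        else:
            X[i, 0] = X[i - 1, 0] - gap_extend
            pX[i, 0] = 1
        for j in range(1, n + 1):
            # diagonal; tie preference: diagonal > deletion > insertion
            best = M[i - 1, j - 1]
            p = 0
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if read[i - 1] == ref[j - 1] and read[i - 1] < 4:
                M[i, j] = best + match
            else:
                M[i, j] = best - mismatch
            pM[i, j] = p

            # insertion (gap in reference, consumes read base i-1)
            best = M[i - 1, j] - open_cost
            p = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                p = 1
            if Y[i - 1, j] - open_cost > best:
                best = Y[i - 1, j] - open_cost
                p = 2
            X[i, j] = best
            pX[i, j] = p

            # deletion (gap in read, consumes reference base j-1)
            best = M[i, j - 1] - open_cost
            p = 0
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                p = 2
            if X[i, j - 1] - open_cost > best:
                best = X[i, j - 1] - open_cost
                p = 1
            Y[i, j] = best
            pY[i, j] = p

    return M, X, Y, pM, pX, pY
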