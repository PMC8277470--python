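"""Numba kernel for optimal affine-gap pairwise alignment.

Three-state Gotoh dynamic programme (match state M, vertical-gap state X
consuming sequence a, horizontal-gap state Y consuming sequence b). A gap
of length L costs gap_open + L * gap_extend. Traceback pointers are stored
per state; tie-breaking is fixed to prefer M (diagonal), then X (up), then
Y (left) so alignments are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.float32(-1e30)

# traceback codes: predecessor state of the current cell/state
M_FROM_M, M_FROM_X, M_FROM_Y, M_START = 0, 1, 2, 3
G_FROM_M, G_FROM_SELF = 0, 1


@njit(cache=False)
def _fill(a, b, submat, gap_open, gap_ext, local):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    M = np.empty((n + 1, m + 1), dtype=np.float32)
    X = np.empty((n + 1, m + 1), dtype=np.float32)
    Y = np.empty((n + 1, m + 1), dtype=np.float32)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.uint8)

    open_cost = gap_open + gap_ext

    M[0, 0] = 0.0
    X[0, 0] = NEG_INF
    Y[0, 0] = NEG_INF
    for i in range(1, n + 1):
        M[i, 0] = 0.0 if local else NEG_INF
        ptrM[i, 0] = M_START
        X[i, 0] = NEG_INF if local else -(gap_open + gap_ext * i)
        ptrX[i, 0] = G_FROM_SELF
        Y[i, 0] = NEG_INF
    for j in range(1, m + 1):
        M[0, j] = 0.0 if local else NEG_INF
        ptrM[0, j] = M_START
        Y[0, j] = NEG_INF if local else -(gap_open + gap_ext * j)
        ptrY[0, j] = G_FROM_SELF
        X[0, j] = NEG_INF

    best_score = NEG_INF
    best_i = 0
    best_j = 0
    best_state = 0

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = submat[ai, b[j - 1]]
            # M: diagonal move; prefer predecessor M > X > Y on ties
            vm, px = M[i - 1, j - 1], M_FROM_M
            if X[i - 1, j - 1] > vm:
                vm, px = X[i - 1, j - 1], M_FROM_X
            if Y[i - 1, j - 1] > vm:
                vm, px = Y[i - 1, j - 1], M_FROM_Y
            vm = vm + s
            if local and vm < 0.0:
                vm = 0.0
                px = M_START
            M[i, j] = vm
            ptrM[i, j] = px

            # X: vertical (gap in b, consumes a[i-1]); open from M, extend in X
            vo = M[i - 1, j] - open_cost
            ve = X[i - 1, j] - gap_ext
            if vo >= ve:
                X[i, j] = vo
                ptrX[i, j] = G_FROM_M
            else:
                X[i, j] = ve
                ptrX[i, j] = G_FROM_SELF

            # Y: horizontal (gap in a, consumes b[j-1])
            vo = M[i, j - 1] - open_cost
            ve = Y[i, j - 1] - gap_ext
            if vo >= ve:
                Y[i, j] = vo
                ptrY[i, j] = G_FROM_M
            else:
                Y[i, j] = ve
                ptrY[i, j] = G_FROM_SELF

            if local and M[i, j] > best_score:
                best_score = M[i, j]
                best_i, best_j, best_state = i, j, 0

    if not local:
        best_i, best_j = n, m
        best_score, best_state = M[n, m], 0
        if X[n, m] > best_score:
            best_score, best_state = X[n, m], 1
        if Y[n, m] > best_score:
            best_score, best_state = Y[n, m], 2

    return M, X, Y, ptrM, ptrX, ptrY, best_score, best_i, best_j, best_state


def affine_align(
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    submat: np.ndarray,
    gap_open: float,
    gap_ext: float,
    local: bool,
):
    """Run the DP and trace back one optimal alignment.

    Returns (score, ops, a_span, b_span) where ops is a list of column
    operations 'M' (both advance), 'X' (a advances, gap in b) or 'Y'
    (b advances, gap in a), in alignment order.
    """
    (M, X, Y, ptrM, ptrX, ptrY, score, i, j, state) = _fill(
        a_codes,
        b_codes,
        submat.astype(np.float32),
        np.float32(gap_open),
        np.float32(gap_ext),
        local,
    )
    ops: list = []
    a_end, b_end = i, j
    while i > 0 or j > 0:
        if state == 0:  # M
            if i == 0 and j == 0:
                break
            p = ptrM[i, j]
            if p == M_START:
                break
            ops.append("M")
            i -= 1
            j -= 1
            state = int(p)
        elif state == 1:  # X (up)
            p = ptrX[i, j]
            ops.append("X")
            i -= 1
            state = 0 if p == G_FROM_M else 1
        else:  # Y (left)
            p = ptrY[i, j]
            ops.append("Y")
            j -= 1
            state = 0 if p == G_FROM_M else 2
    ops.reverse()
    return float(score), ops, (i, a_end), (j, b_end)
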