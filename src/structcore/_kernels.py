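"""Numba dynamic-programming kernels for pairwise and profile alignment.

All kernels take a precomputed position-pair score matrix, so the same code
serves combined 3Di+AA scoring, AA-only scoring, and profile-column scoring.
Tie-breaking is fixed ("high road"): on equal scores the diagonal move is
preferred, then the vertical move (gap in the second sequence/profile), then
the horizontal move.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -10**9


@njit(cache=True)
def local_align_stats(S, gap_open, gap_extend):
    """Optimal local (Smith-Waterman) affine-gap alignment: score and span.

    Parameters: S (n x m int32 score matrix), affine penalties.
    Returns (best, qs, qe, ts, te): best raw score and the 0-based inclusive
    start/end coordinates of the optimal local path in each sequence
    (all -1 when best == 0). Start coordinates are propagated through the DP
    so no traceback matrix is materialised.
    """
    n, m = S.shape
    H_prev = np.zeros(m + 1, dtype=np.int64)
    H_cur = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, NEG, dtype=np.int64)
    # start coordinates carried along with each state
    Hs_prev = np.full((m + 1, 2), -1, dtype=np.int64)
    Hs_cur = np.full((m + 1, 2), -1, dtype=np.int64)
    Fs = np.full((m + 1, 2), -1, dtype=np.int64)

    best = 0
    bqs = bqe = bts = bte = -1
    for i in range(1, n + 1):
        e = NEG
        es_r = es_c = -1
        H_cur[0] = 0
        Hs_cur[0, 0] = -1
        Hs_cur[0, 1] = -1
        for j in range(1, m + 1):
            # E: gap in first sequence (move left)
            open_e = H_cur[j - 1] - gap_open
            ext_e = e - gap_extend
            if open_e >= ext_e:
                e = open_e
                es_r = Hs_cur[j - 1, 0]
                es_c = Hs_cur[j - 1, 1]
            else:
                e = ext_e
            # F: gap in second sequence (move up)
            open_f = H_prev[j] - gap_open
            ext_f = F[j] - gap_extend
            if open_f >= ext_f:
                F[j] = open_f
                Fs[j, 0] = Hs_prev[j, 0]
                Fs[j, 1] = Hs_prev[j, 1]
            else:
                F[j] = ext_f
            diag = H_prev[j - 1] + S[i - 1, j - 1]
            if H_prev[j - 1] == 0:
                dr, dc = i - 1, j - 1
            else:
                dr, dc = Hs_prev[j - 1, 0], Hs_prev[j - 1, 1]
            # high-road preference: diag >= F (up) >= E (left) >= 0
            h = diag
            hr, hc = dr, dc
            if F[j] > h:
                h = F[j]
                hr, hc = Fs[j, 0], Fs[j, 1]
            if e > h:
                h = e
                hr, hc = es_r, es_c
            if h < 0:
                h = 0
                hr, hc = -1, -1
            H_cur[j] = h
            Hs_cur[j, 0] = hr
            Hs_cur[j, 1] = hc
            if h > best:
                best = h
                bqs, bts = hr, hc
                bqe, bte = i - 1, j - 1
        H_prev, H_cur = H_cur, H_prev
        Hs_prev, Hs_cur = Hs_cur, Hs_prev
    return best, bqs, bqe, bts, bte


@njit(cache=True)
def local_align_traceback(S, gap_open, gap_extend):
    """Local affine alignment with full traceback.

    Returns (best, qa, ta) where qa/ta are int32 arrays of equal length over
    the aligned columns: 0-based positions, -1 for a gap in that sequence.
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    # pointers: for H: 0=stop, 1=diag, 2=from F (up), 3=from E (left)
    PH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = opened from H
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)

    best = 0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            open_e = H[i, j - 1] - gap_open
            ext_e = E[i, j - 1] - gap_extend
            if open_e >= ext_e:
                E[i, j] = open_e
                PE[i, j] = 1
            else:
                E[i, j] = ext_e
            open_f = H[i - 1, j] - gap_open
            ext_f = F[i - 1, j] - gap_extend
            if open_f >= ext_f:
                F[i, j] = open_f
                PF[i, j] = 1
            else:
                F[i, j] = ext_f
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            h = diag
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j

    qa = np.empty(n + m, dtype=np.int64)
    ta = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                qa[k] = i - 1
                ta[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: gap in first sequence, consumes j
            qa[k] = -1
            ta[k] = j - 1
            k += 1
            if PE[i, j] == 1:
                state = 0
            j -= 1
        else:  # F: gap in second sequence, consumes i
            qa[k] = i - 1
            ta[k] = -1
            k += 1
            if PF[i, j] == 1:
                state = 0
            i -= 1
    return best, qa[:k][::-1].copy(), ta[:k][::-1].copy()


@njit(cache=True)
def global_align_profile(S, gap_open, gap_extend):
    """Global (Needleman-Wunsch) affine-gap alignment of two column sets.

    S is an (n x m) float64 matrix of column-pair scores. Terminal gaps are
    penalised like internal ones. Returns (score, qa, ta) with the same
    column-path encoding as :func:`local_align_traceback`; every input column
    appears exactly once.
    """
    n, m = S.shape
    NEGF = -1e18
    M = np.full((n + 1, m + 1), NEGF)
    E = np.full((n + 1, m + 1), NEGF)
    F = np.full((n + 1, m + 1), NEGF)
    PM = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1=diag,2=F,3=E
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -gap_open - (j - 1) * gap_extend
        PE[0, j] = 1 if j == 1 else 0
    for i in range(1, n + 1):
        F[i, 0] = -gap_open - (i - 1) * gap_extend
        PF[i, 0] = 1 if i == 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            open_e = max(M[i, j - 1], F[i, j - 1]) - gap_open
            ext_e = E[i, j - 1] - gap_extend
            if open_e >= ext_e:
                E[i, j] = open_e
                PE[i, j] = 1
            else:
                E[i, j] = ext_e
            open_f = max(M[i - 1, j], E[i - 1, j]) - gap_open
            ext_f = F[i - 1, j] - gap_extend
            if open_f >= ext_f:
                F[i, j] = open_f
                PF[i, j] = 1
            else:
                F[i, j] = ext_f
            best_prev = M[i - 1, j - 1]
            if E[i - 1, j - 1] > best_prev:
                best_prev = E[i - 1, j - 1]
            if F[i - 1, j - 1] > best_prev:
                best_prev = F[i - 1, j - 1]
            M[i, j] = best_prev + S[i - 1, j - 1]
            PM[i, j] = 1

    # terminal cell: choose best state, high-road order M >= F >= E
    i, j = n, m
    score = M[n, m]
    state = 0
    if F[n, m] > score:
        score = F[n, m]
        state = 2
    if E[n, m] > score:
        score = E[n, m]
        state = 1
    qa = np.empty(n + m, dtype=np.int64)
    ta = np.empty(n + m, dtype=np.int64)
    k = 0
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                state = 1 if i == 0 else 2
                continue
            qa[k] = i - 1
            ta[k] = j - 1
            k += 1
            i -= 1
            j -= 1
            # which state fed this M cell?
            prev = M[i, j]
            st = 0
            if E[i, j] > prev:
                prev = E[i, j]
                st = 1
            if F[i, j] > prev:
                prev = F[i, j]
                st = 2
            # high-road: prefer M on ties
            if M[i, j] >= prev:
                st = 0
            state = st
        elif state == 1:  # E consumes j
            qa[k] = -1
            ta[k] = j - 1
            k += 1
            opened = PE[i, j] == 1
            j -= 1
            if opened:
                state = 0 if M[i, j] >= F[i, j] else 2
        else:  # F consumes i
            qa[k] = i - 1
            ta[k] = -1
            k += 1
            opened = PF[i, j] == 1
            i -= 1
            if opened:
                state = 0 if M[i, j] >= E[i, j] else 1
    return score, qa[:k][::-1].copy(), ta[:k][::-1].copy()
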