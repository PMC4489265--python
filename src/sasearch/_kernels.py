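"""Numba kernels for local dynamic-programming alignment.

Affine gap convention: a gap of length k costs gap_open + k * gap_extend
(the NCBI/BLAST convention, so the bundled Karlin–Altschul constants
apply).  Scores are int32 in substitution-matrix units.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10 ** 9) // 2)

# traceback codes for the H (match) state
STOP, DIAG, UP, LEFT = 0, 1, 2, 3


@njit(cache=True)
def sw_score(q, t, mat, gap_open, gap_extend):
    """Score-only unbanded Smith–Waterman with affine gaps.

    q, t: uint8 residue codes (1-based into mat via code-1).
    Returns the best local alignment score (>= 0).
    """
    lt = t.shape[0]
    h_prev = np.zeros(lt + 1, dtype=np.int32)
    e_prev = np.full(lt + 1, NEG, dtype=np.int32)
    open_cost = np.int32(gap_open + gap_extend)
    ext = np.int32(gap_extend)
    best = np.int32(0)
    for i in range(q.shape[0]):
        qi = q[i] - 1
        h_diag = np.int32(0)
        f = NEG
        h_here = np.int32(0)
        for j in range(1, lt + 1):
            e = max(h_prev[j] - open_cost, e_prev[j] - ext)
            f = max(h_here - open_cost, f - ext)
            h = h_diag + mat[qi, t[j - 1] - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = np.int32(0)
            if h > best:
                best = h
            h_diag = h_prev[j]
            h_prev[j] = h
            e_prev[j] = e
            h_here = h
        h_prev[0] = 0
    return best


@njit(cache=True)
def sw_score_many(q, targets_codes, starts, lengths, mat, gap_open, gap_extend):
    """Smith–Waterman score of ``q`` against many concatenated targets.

    targets_codes holds all target code arrays back to back; target k is
    targets_codes[starts[k] : starts[k] + lengths[k]].
    """
    out = np.zeros(starts.shape[0], dtype=np.int32)
    for k in range(starts.shape[0]):
        t = targets_codes[starts[k]:starts[k] + lengths[k]]
        out[k] = sw_score(q, t, mat, gap_open, gap_extend)
    return out


@njit(cache=True)
def banded_sw(q, t, mat, gap_open, gap_extend, center, half_band):
    """Banded Smith–Waterman with affine gaps and traceback pointers.

    Cells (i, j) of the (len(q)+1) x (len(t)+1) DP matrix are filled only
    where the diagonal i - j lies within half_band of center.  Traceback
    ties prefer diagonal, then up (gap in target), then left (gap in
    query).

    Returns (score, best_i, best_j, ph, pe, pf) where ph holds the H-state
    move codes and pe/pf record whether the E/F gap states opened (1) or
    extended (0).
    """
    lq = q.shape[0]
    lt = t.shape[0]
    h = np.zeros((lq + 1, lt + 1), dtype=np.int32)
    e = np.full((lq + 1, lt + 1), NEG, dtype=np.int32)
    f = np.full((lq + 1, lt + 1), NEG, dtype=np.int32)
    ph = np.zeros((lq + 1, lt + 1), dtype=np.uint8)
    pe = np.zeros((lq + 1, lt + 1), dtype=np.uint8)
    pf = np.zeros((lq + 1, lt + 1), dtype=np.uint8)
    open_cost = np.int32(gap_open + gap_extend)
    ext = np.int32(gap_extend)
    best = np.int32(0)
    best_i = 0
    best_j = 0
    for i in range(1, lq + 1):
        jlo = i - center - half_band
        jhi = i - center + half_band
        if jlo < 1:
            jlo = 1
        if jhi > lt:
            jhi = lt
        for j in range(jlo, jhi + 1):
            ev_open = h[i, j - 1] - open_cost
            ev_ext = e[i, j - 1] - ext
            if ev_open >= ev_ext:
                ev = ev_open
                pe[i, j] = 1
            else:
                ev = ev_ext
                pe[i, j] = 0
            e[i, j] = ev
            fv_open = h[i - 1, j] - open_cost
            fv_ext = f[i - 1, j] - ext
            if fv_open >= fv_ext:
                fv = fv_open
                pf[i, j] = 1
            else:
                fv = fv_ext
                pf[i, j] = 0
            f[i, j] = fv
            dv = h[i - 1, j - 1] + mat[q[i - 1] - 1, t[j - 1] - 1]
            # tie priority: diagonal, then up (F), then left (E)
            hv = dv
            move = DIAG
            if fv > hv:
                hv = fv
                move = UP
            if ev > hv:
                hv = ev
                move = LEFT
            if hv <= 0:
                hv = np.int32(0)
                move = STOP
            h[i, j] = hv
            ph[i, j] = move
            if hv > best:
                best = hv
                best_i = i
                best_j = j
    return best, best_i, best_j, ph, pe, pf
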