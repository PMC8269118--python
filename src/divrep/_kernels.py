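"""Numba kernels for the cyclic local-alignment dynamic program.

The recurrence (sequence index i along rows, probe index j along columns) is

    F(i,j) = max{ 0,
                  F(i-1,j-1) + MT(s1(j), t),   # match
                  F(i,j-1) - del,              # gap in sequence
                  F(i-1,j) - del }             # gap in probe

where t is the pair category formed by the current sequence symbol and the
symbol of the *previous sequence position consumed on the best path into the
diagonal predecessor*.  Each cell therefore stores, besides F, the symbol of
that last-consumed position (``SY``, 1..5; 0 when none exists).  The first
aligned column of a local path has no in-alignment predecessor and
contributes 0; a cell floored at 0 starts a fresh path consuming (i, j).

Tie-breaking: match > gap-in-sequence > gap-in-probe; among equal maxima of F
the smallest (i, j) wins.  For speed the row fill is split into an
independent pass (match / gap-in-probe candidates) and a sequential pass (the
gap-in-sequence scan) to shorten the loop-carried dependency chain, and the
match score is read from a per-symbol lookup table ``tab[si][row][SY]`` whose
column 0 (no predecessor) is zero, making the hot loop branchless.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Move codes stored per cell.
MOVE_STOP = 0   # F == 0: path starts here (or cell is dead)
MOVE_DIAG = 1
MOVE_GAP_SEQ = 2    # probe advances, sequence gapped
MOVE_GAP_PROBE = 3  # sequence advances, probe gapped


@njit(cache=True, fastmath=True)
def _fill(seq0, probe_row, tab, del_pen, F, SY, MV, dv):  # pragma: no cover
    L = seq0.shape[0]
    best = np.float32(0.0)
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        si = seq0[i - 1]
        Fi = F[i]
        Fim = F[i - 1]
        Si = SY[i]
        Sim = SY[i - 1]
        Mi = MV[i]
        trow = tab[si]
        for j in range(1, L + 1):
            d = Fim[j - 1] + trow[probe_row[j - 1], Sim[j - 1]]
            b = Fim[j] - del_pen
            if b > d:
                dv[j] = b
                Mi[j] = MOVE_GAP_PROBE
            else:
                dv[j] = d
                Mi[j] = MOVE_DIAG
        sip1 = si + 1
        for j in range(1, L + 1):
            v = dv[j]
            mv = Mi[j]
            p = sip1
            a = Fi[j - 1] - del_pen
            # gap-in-sequence outranks gap-in-probe on ties but not the match
            if a > v or (a == v and mv == MOVE_GAP_PROBE):
                v = a
                mv = MOVE_GAP_SEQ
                p = Si[j - 1]
            if v <= 0.0:
                v = np.float32(0.0)
                mv = MOVE_STOP
                p = sip1
            Fi[j] = v
            Si[j] = p
            Mi[j] = mv
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _traceback(F, MV, bi, bj):  # pragma: no cover
    """Walk moves from the maximum back to the first zero cell.

    Returns (seq_pos, probe_pos) per column, oldest first, -1 marking a gap.
    The zero cell itself is the first aligned column of the path (it consumed
    (i, j) with zero contribution), provided it is an interior cell.
    """
    cap = 4 * (F.shape[0] + F.shape[1])
    sp = np.empty(cap, np.int32)
    pp = np.empty(cap, np.int32)
    m = 0
    i = bi
    j = bj
    while i > 0 and j > 0 and F[i, j] > 0.0:
        mv = MV[i, j]
        if mv == MOVE_DIAG:
            sp[m] = i
            pp[m] = j
            i -= 1
            j -= 1
        elif mv == MOVE_GAP_SEQ:
            sp[m] = -1
            pp[m] = j
            j -= 1
        else:  # MOVE_GAP_PROBE
            sp[m] = i
            pp[m] = -1
            i -= 1
        m += 1
    if i > 0 and j > 0:
        # interior zero cell: path start, aligned with zero contribution
        sp[m] = i
        pp[m] = j
        m += 1
    return sp[:m][::-1].copy(), pp[:m][::-1].copy()


def score_table(mt: np.ndarray) -> np.ndarray:
    """(5, n, 6) lookup: tab[cur_sym][probe_row][prev_sym + 1], zero when the
    previous symbol does not exist (column 0)."""
    n = mt.shape[0]
    tab = np.zeros((5, n, 6), np.float32)
    for si in range(5):
        tab[si, :, 1:] = mt[:, 5 * si: 5 * si + 5]
    return tab


# Reusable DP buffers keyed by sequence length.  Only row 0 and column 0 are
# boundary cells and they are never written, so a buffer can be reused without
# re-zeroing: the fill overwrites every interior cell before reading it.
_BUFFERS: dict[int, tuple] = {}


def _buffers(L: int):
    buf = _BUFFERS.get(L)
    if buf is None:
        if len(_BUFFERS) > 8:
            _BUFFERS.clear()
        buf = (
            np.zeros((L + 1, L + 1), np.float32),
            np.zeros((L + 1, L + 1), np.uint8),  # SY: 0 = no predecessor
            np.zeros((L + 1, L + 1), np.uint8),
            np.zeros(L + 1, np.float32),
        )
        _BUFFERS[L] = buf
    return buf


def align_kernel(seq_symbols: np.ndarray, n: int, mt: np.ndarray, del_pen: float):
    """Run fill + traceback.  Returns (score, seq_pos, probe_pos) with 1-based
    positions per column and -1 for gaps."""
    L = len(seq_symbols)
    seq0 = np.ascontiguousarray(np.asarray(seq_symbols, dtype=np.int64) - 1)
    probe_row = (np.arange(L, dtype=np.int64) % n).astype(np.int16)
    tab = score_table(np.asarray(mt, dtype=np.float32))
    F, SY, MV, dv = _buffers(L)
    best, bi, bj = _fill(seq0, probe_row, tab, np.float32(del_pen), F, SY, MV, dv)
    if best <= 0.0:
        empty = np.empty(0, np.int32)
        return 0.0, empty, empty
    sp, pp = _traceback(F, MV, bi, bj)
    return float(best), sp, pp
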