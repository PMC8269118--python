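"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most literal route possible
(explicit enumeration, cell-by-cell loops) and share no code with the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def exact_alignment_score(seq, n, mt, del_pen=25.0) -> float:
    """Maximum over all monotone local paths of the path-dependent score.

    A path is a sequence of columns; the first aligned column contributes 0,
    a later match at (i, j) adds mt[(j-1) % n, (s[k]-1) + 5*(s[i]-1)] with k
    the path's previously consumed sequence position, and each gap costs
    ``del_pen``.  Computed by exhaustive dynamic programming over the state
    (i, j, last consumed position) — exponentially many paths collapse onto
    polynomially many states without any heuristic.
    """
    seq = np.asarray(seq, dtype=np.int64)
    L = len(seq)
    G = np.full((L + 1, L + 1, L + 1), NEG)
    best = 0.0
    for i in range(1, L + 1):
        for j in range(1, L + 1):
            row = (j - 1) % n
            # match: from (i-1, j-1, k') plus the pair score, or a fresh start
            m = 0.0
            if i > 1:
                prev = G[i - 1, j - 1, 1:i]
                pair = (seq[0:i - 1] - 1) + 5 * (seq[i - 1] - 1)
                cand = prev + mt[row, pair]
                m = max(m, cand.max())
            # gap in probe: consumes i, any previous k'
            gp = NEG
            if i > 1:
                gp = G[i - 1, j, 1:i].max() - del_pen
            G[i, j, i] = max(m, gp)
            # gap in sequence: k unchanged
            gs = G[i, j - 1, : i + 1] - del_pen
            G[i, j, : i + 1] = np.maximum(G[i, j, : i + 1], gs)
            best = max(best, G[i, j, : i + 1].max())
    return best


def replay_alignment_score(local, mt, del_pen=25.0) -> float:
    """Re-score a traceback path column by column through the scoring rule."""
    score = 0.0
    last_sym = None
    first = True
    for spos, ppos, ssym, psym in zip(
        local.seq_positions, local.probe_positions,
        local.seq_symbols, local.probe_symbols,
    ):
        if spos > 0 and ppos > 0:  # match column
            if not first and last_sym is not None:
                row = (ppos - 1) % local.n
                score += float(
                    np.float32(mt[row, (last_sym - 1) + 5 * (ssym - 1)])
                )
            last_sym = int(ssym)
            first = False
        elif ppos > 0:  # gap in sequence
            score -= del_pen
        else:  # gap in probe
            score -= del_pen
            last_sym = int(ssym)
    return score


def weights_by_hand(counts: np.ndarray) -> np.ndarray:
    """Cell-by-cell evaluation of the standardized-residual formula."""
    counts = np.asarray(counts, dtype=float)
    n, c = counts.shape
    total = counts.sum()
    out = np.zeros_like(counts)
    for i in range(n):
        for j in range(c):
            x = counts[i, :].sum()
            y = counts[:, j].sum()
            p = x * y / total**2
            if p > 0 and p < 1:
                out[i, j] = (counts[i, j] - total * p) / np.sqrt(
                    total * p * (1 - p)
                )
    return out


def cyclic_distance_by_hand(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum rooted Euclidean distance over explicit row rotations."""
    n = a.shape[0]
    best = np.inf
    for shift in range(n):
        rotated = np.vstack([b[(i - shift) % n] for i in range(n)])
        best = min(best, float(np.sqrt(((a - rotated) ** 2).sum())))
    return best


def divergence_by_hand(rows: list[str]) -> tuple[int, int, float]:
    """Recount v, v1 and S from a gap-annotated row list ('.' = gap)."""
    k = len(rows)
    width = len(rows[0])
    v = 0
    v1 = 0
    for j in range(width):
        col = [r[j] for r in rows if r[j] != "."]
        if len(col) < k / 2:
            continue
        counts: dict[str, int] = {}
        for sym in col:
            counts[sym] = counts.get(sym, 0) + 1
        v += max(counts.values())
        v1 += len(col)
    return v, v1, 1.0 - v / v1
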