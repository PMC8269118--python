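"""Local alignment of a recoded sequence against the cyclic probe.

The probe encodes the repeat phase: aligning the sequence to the probe under
a pair-correlation weight matrix finds the sequence region whose symbol pairs
follow the matrix's periodic preferences.  Scoring uses the Smith-Waterman
style recurrence documented in :mod:`divrep._kernels`, with a linear indel
penalty (default 25.0).  Because the match score at a column depends on the
previous sequence symbol consumed by the path, the cell-local dynamic program
is a heuristic: each cell keeps a single best (score, last-symbol) state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import align_kernel
from .alphabet import GROUP_LETTERS
from .pwm import NormalizedWeightMatrix, PeriodicProbe

DEFAULT_DEL_PENALTY = 25.0


@dataclass(frozen=True)
class LocalAlignment:
    """A traceback path between the cyclic probe and a sequence.

    ``seq_positions`` / ``probe_positions`` give the 1-based position consumed
    at each column (-1 marks a gap on that side); ``seq_symbols`` /
    ``probe_symbols`` the corresponding symbols (-1 at gaps).  ``score`` is
    mF, the maximum of the similarity matrix; an empty alignment (mF = 0) has
    zero-length arrays.
    """

    score: float
    n: int
    seq_positions: np.ndarray
    probe_positions: np.ndarray
    seq_symbols: np.ndarray
    probe_symbols: np.ndarray

    @property
    def is_empty(self) -> bool:
        return len(self.seq_positions) == 0

    @property
    def aligned_pairs(self) -> int:
        """Number of match columns."""
        return int(
            np.count_nonzero((self.seq_positions > 0) & (self.probe_positions > 0))
        )

    @property
    def seq_start(self) -> int:
        return int(self.seq_positions[self.seq_positions > 0].min()) if not self.is_empty else 0

    @property
    def seq_end(self) -> int:
        return int(self.seq_positions[self.seq_positions > 0].max()) if not self.is_empty else 0

    @property
    def probe_start(self) -> int:
        return int(self.probe_positions[self.probe_positions > 0].min()) if not self.is_empty else 0

    @property
    def probe_end(self) -> int:
        return int(self.probe_positions[self.probe_positions > 0].max()) if not self.is_empty else 0

    @property
    def seq_span(self) -> int:
        """Sequence-side span r - l + 1 (0 for an empty alignment)."""
        return self.seq_end - self.seq_start + 1 if not self.is_empty else 0


def local_align(
    mt: NormalizedWeightMatrix,
    probe: PeriodicProbe,
    seq,
    del_penalty: float = DEFAULT_DEL_PENALTY,
) -> LocalAlignment:
    """Best local alignment of ``seq`` against ``probe`` under matrix ``mt``.

    The probe length must equal the sequence length (the probe is rebuilt per
    sequence by the caller) and the matrix must have ``probe.n`` rows.
    """
    symbols = np.asarray(seq.symbols if hasattr(seq, "symbols") else seq, dtype=np.int8)
    if probe.L != len(symbols):
        raise ValueError(f"probe length {probe.L} != sequence length {len(symbols)}")
    if mt.matrix.shape[0] != probe.n:
        raise ValueError(
            f"matrix has {mt.matrix.shape[0]} rows but probe period is {probe.n}"
        )
    score, sp, pp = align_kernel(symbols, probe.n, mt.matrix, del_penalty)
    seq_syms = np.where(sp > 0, symbols[np.maximum(sp - 1, 0)].astype(np.int16), -1)
    probe_syms = np.where(pp > 0, probe.symbols[np.maximum(pp - 1, 0)].astype(np.int16), -1)
    return LocalAlignment(
        score=score,
        n=probe.n,
        seq_positions=sp,
        probe_positions=pp,
        seq_symbols=seq_syms.astype(np.int16),
        probe_symbols=probe_syms.astype(np.int16),
    )


def render_alignment(local: LocalAlignment) -> str:
    """Two-line dot rendering: probe consensus positions vs. group letters.

    Gaps are printed as '.' on the gapped side, matching the convention used
    for repeat multiple-alignment tables.
    """
    if local.is_empty:
        return ""
    top = []
    bottom = []
    for ppos, ssym in zip(local.probe_positions, local.seq_symbols):
        top.append(str((ppos - 1) % local.n + 1) if ppos > 0 else ".")
        bottom.append(GROUP_LETTERS[ssym - 1] if ssym > 0 else ".")
    width = max(len(t) for t in top)
    line1 = " ".join(t.rjust(width) for t in top)
    line2 = " ".join(b.rjust(width) for b in bottom)
    return line1 + "\n" + line2
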