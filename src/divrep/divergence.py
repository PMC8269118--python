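"""Repeat multiple alignment and divergence degree S.

The sequence side of a local alignment is cut at probe-period boundaries:
each period of the cyclic probe contributes one row of the repeat multiple
alignment.  Sequence symbols consumed against a gapped probe position become
insertion columns; probe positions aligned to a gapped sequence, and positions
not covered by a partial first/last copy, are '.' cells.

From the alignment with k rows, columns holding fewer than k/2 residues are
disregarded; the per-column modal symbol is the consensus, and the divergence
degree is

    S = 1 - v / v1

with v the number of retained residues matching their column consensus and v1
the total number of retained residues.  S = 0 means perfectly conserved
copies; S > 0.5 marks highly divergent repeats.

S can be computed in the 5-letter group space the detector works in
(``groups5``) or, via provenance, over the original residues
(``residues20``, the default used in reports).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import GROUP_LETTERS, RecodedSequence
from .cyclic_align import LocalAlignment
from .errors import EmptyAfterFilterError, TooFewRepeatsError

GAP = "."
#: Fixed consensus tie-break orders (smaller index wins).
_GROUP_ORDER = GROUP_LETTERS
_RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class RepeatMultipleAlignment:
    """k repeat copies x n1 columns, in both symbol spaces.

    ``group_rows`` hold 5-letter group codes, ``residue_rows`` the original
    amino acids; '.' marks gaps in both.  ``n1 >= n`` when insertion columns
    are present.
    """

    n: int
    group_rows: tuple[str, ...]
    residue_rows: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.group_rows)

    @property
    def n1(self) -> int:
        return len(self.group_rows[0])

    def render(self, symbol_space: str = "groups5") -> str:
        """Numbered plain-text block in the dot convention."""
        rows = self.group_rows if symbol_space == "groups5" else self.residue_rows
        width = len(str(len(rows)))
        return "\n".join(
            f"{i + 1:>{width}}  {row}" for i, row in enumerate(rows)
        )

    def to_tsv(self, symbol_space: str = "groups5") -> str:
        """Machine-readable export: one row per repeat copy, one cell per
        alignment column."""
        rows = self.group_rows if symbol_space == "groups5" else self.residue_rows
        header = "copy\t" + "\t".join(f"c{j + 1}" for j in range(self.n1))
        body = [f"{i + 1}\t" + "\t".join(row) for i, row in enumerate(rows)]
        return "\n".join([header, *body]) + "\n"


@dataclass(frozen=True)
class DivergenceResult:
    consensus: str
    v: int
    v1: int
    s: float


def repeats_from_alignment(
    local: LocalAlignment, seq: RecodedSequence
) -> RepeatMultipleAlignment:
    """Slice the sequence side of a local alignment into repeat rows."""
    if local.is_empty:
        raise TooFewRepeatsError("empty alignment")
    n = local.n
    # cells[(copy, within-period pos)] and insertions[(copy, pos, rank)]
    cells: dict[tuple[int, int], tuple[str, str]] = {}
    insertions: dict[tuple[int, int, int], tuple[str, str]] = {}
    ins_depth: dict[int, int] = {}  # pos -> max insertion run length
    last_copy = None
    last_pos = None
    run = 0
    copies: set[int] = set()
    for spos, ppos in zip(local.seq_positions, local.probe_positions):
        if ppos > 0:
            copy = (ppos - 1) // n
            pos = (ppos - 1) % n
            copies.add(copy)
            last_copy, last_pos = copy, pos
            run = 0
            if spos > 0:
                g = GROUP_LETTERS[seq.symbols[spos - 1] - 1]
                r = seq.residue_at(spos - 1)
                cells[(copy, pos)] = (g, r)
            else:
                cells[(copy, pos)] = (GAP, GAP)
        else:
            # sequence symbol inserted after the last consumed probe position
            g = GROUP_LETTERS[seq.symbols[spos - 1] - 1]
            r = seq.residue_at(spos - 1)
            insertions[(last_copy, last_pos, run)] = (g, r)
            ins_depth[last_pos] = max(ins_depth.get(last_pos, 0), run + 1)
            run += 1
    if len(copies) < 2:
        raise TooFewRepeatsError(
            f"alignment covers {len(copies)} repeat copy(ies); need at least 2"
        )
    copy_ids = sorted(copies)
    group_rows = []
    residue_rows = []
    for copy in copy_ids:
        grow = []
        rrow = []
        for pos in range(n):
            g, r = cells.get((copy, pos), (GAP, GAP))
            grow.append(g)
            rrow.append(r)
            for rank in range(ins_depth.get(pos, 0)):
                gi, ri = insertions.get((copy, pos, rank), (GAP, GAP))
                grow.append(gi)
                rrow.append(ri)
        group_rows.append("".join(grow))
        residue_rows.append("".join(rrow))
    return RepeatMultipleAlignment(
        n=n, group_rows=tuple(group_rows), residue_rows=tuple(residue_rows)
    )


def divergence_degree(
    rma: RepeatMultipleAlignment, symbol_space: str = "residues20"
) -> DivergenceResult:
    """Consensus and divergence degree S = 1 - v/v1 of a repeat alignment.

    Columns with fewer than k/2 residues are disregarded (a column holding
    exactly k/2 is retained).  Consensus ties resolve to the symbol with the
    smaller fixed index (group order K,N,I,M,T; residues alphabetically).
    """
    if symbol_space == "groups5":
        rows, order = rma.group_rows, _GROUP_ORDER
    elif symbol_space == "residues20":
        rows, order = rma.residue_rows, _RESIDUE_ORDER
    else:
        raise ValueError(f"unknown symbol_space {symbol_space!r}")
    k = len(rows)
    if k < 2:
        raise TooFewRepeatsError("need at least 2 repeat rows")
    grid = np.array([list(r) for r in rows])
    consensus = []
    v = 0
    v1 = 0
    for j in range(grid.shape[1]):
        col = grid[:, j]
        residues = col[col != GAP]
        if len(residues) < k / 2:
            continue
        counts = {sym: 0 for sym in order}
        for sym in residues:
            counts[sym] += 1
        best = max(order, key=lambda sym: counts[sym])  # max() keeps first tie
        consensus.append(best)
        v += counts[best]
        v1 += len(residues)
    if v1 == 0:
        raise EmptyAfterFilterError("all columns removed by the k/2 filter")
    return DivergenceResult(consensus="".join(consensus), v=v, v1=v1, s=1.0 - v / v1)
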