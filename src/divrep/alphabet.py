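"""Reduced five-letter physicochemical alphabet.

The 20 standard amino acids are partitioned by side-chain polarity into five
groups, each named by a single letter:

====== ===================== =================
symbol group letter          residues
====== ===================== =================
1      K (non-polar)         G A V I L P
2      N (polar)             S T C M Q N
3      I (aromatic)          F Y W
4      M (positively charged) K R H
5      T (negatively charged) D E
====== ===================== =================

All downstream scoring operates on the 5-symbol recoding; original residues
are kept alongside so that reported coordinates and 20-letter consensus
statistics can be mapped back to the input protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlphabetError

#: Group letters in fixed symbol order (symbol 1 -> "K", ..., symbol 5 -> "T").
GROUP_LETTERS = "KNIMT"

#: Residue membership of each group.
GROUPS: dict[str, str] = {
    "K": "GAVILP",
    "N": "STCMQN",
    "I": "FYW",
    "M": "KRH",
    "T": "DE",
}

#: Map residue -> integer symbol in 1..5.
SYMBOL_OF_RESIDUE: dict[str, int] = {
    res: i + 1 for i, letter in enumerate(GROUP_LETTERS) for res in GROUPS[letter]
}


def group_letter(symbol: int) -> str:
    """Group letter (one of K,N,I,M,T) for an integer symbol in 1..5."""
    if not 1 <= symbol <= 5:
        raise ValueError(f"symbol must be in 1..5, got {symbol}")
    return GROUP_LETTERS[symbol - 1]


@dataclass(frozen=True)
class RecodedSequence:
    """A protein recoded into symbols 1..5 with provenance to the original.

    ``positions[i]`` is the 0-based index in ``source`` of the residue behind
    ``symbols[i]``; ``skipped_positions`` lists 0-based indices of
    non-standard residues removed under policy='skip'.
    """

    id: str
    symbols: np.ndarray  # int8, values 1..5
    source: str
    skipped_positions: tuple[int, ...] = ()
    positions: np.ndarray = field(default=None, repr=False)  # int32, 0-based

    def __post_init__(self):
        if self.positions is None:
            object.__setattr__(
                self, "positions", np.arange(len(self.symbols), dtype=np.int32)
            )

    def __len__(self) -> int:
        return len(self.symbols)

    def group_string(self) -> str:
        """The sequence as group letters."""
        return "".join(GROUP_LETTERS[s - 1] for s in self.symbols)

    def residue_at(self, recoded_index: int) -> str:
        """Original residue behind the 0-based recoded position."""
        return self.source[self.positions[recoded_index]]


def recode_sequence(
    protein: str, id: str = "", nonstandard_policy: str = "skip"
) -> RecodedSequence:
    """Recode an amino-acid string into the 5-symbol alphabet.

    Input is upper-cased before lookup.  Non-standard letters (B, J, O, U, X,
    Z, '*', gaps, ...) are removed with their positions recorded under
    policy='skip', or raise :class:`AlphabetError` under policy='error'.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    if nonstandard_policy not in ("skip", "error"):
        raise ValueError(f"unknown nonstandard_policy {nonstandard_policy!r}")
    protein = protein.upper()
    symbols: list[int] = []
    positions: list[int] = []
    skipped: list[int] = []
    for pos, res in enumerate(protein):
        sym = SYMBOL_OF_RESIDUE.get(res)
        if sym is None:
            if nonstandard_policy == "error":
                raise AlphabetError(
                    f"non-standard residue {res!r} at position {pos + 1}"
                )
            skipped.append(pos)
        else:
            symbols.append(sym)
            positions.append(pos)
    return RecodedSequence(
        id=id,
        symbols=np.asarray(symbols, dtype=np.int8),
        source=protein,
        skipped_positions=tuple(skipped),
        positions=np.asarray(positions, dtype=np.int32),
    )
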