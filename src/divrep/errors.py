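"""Exception types raised across the package."""


class DivrepError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(DivrepError):
    """A residue outside the 20-letter standard alphabet under policy='error'."""


class DegenerateMatrixError(DivrepError):
    """A count matrix too degenerate to convert into a weight matrix."""


class NormalizationError(DivrepError):
    """A weight matrix with zero cell variance cannot be normalized."""


class EmptyAlignmentError(DivrepError):
    """An operation that requires a non-empty local alignment got an empty one."""


class TooFewRepeatsError(DivrepError):
    """A local alignment spanning fewer than two repeat copies."""


class EmptyAfterFilterError(DivrepError):
    """All alignment columns were removed by the k/2 occupancy filter."""


class DegenerateNullError(DivrepError):
    """Monte-Carlo null scores had zero variance; Z is undefined."""


class TooShortError(DivrepError):
    """Sequence shorter than the minimum repeat span (14 residues)."""


class UndefinedFDRError(DivrepError):
    """FDR requested with zero hits in the real set."""
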