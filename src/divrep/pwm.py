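"""Pair-correlation position-weight matrices over the cyclic probe.

The detector scores a sequence position not by its own symbol alone but by
the ordered pair (previous symbol, current symbol) — 25 categories over the
5-letter alphabet.  A weight matrix for consensus length ``n`` therefore has
``n`` rows (one per probe position, i.e. per position of the repeat
consensus) and 25 columns (one per symbol pair).

Construction pipeline for the random set Q(n):

1. Build the cyclic probe ``S1 = 1,2,...,n,1,2,...`` of length ``L = 1000 n``
   and a uniform random 5-symbol sequence ``S2`` of the same length.
2. Count adjacent pairs: for i = 2..L increment row ``s1(i)``, column
   ``k = s2(i-1) + 5 (s2(i) - 1)``; the counts sum to ``L - 1``.
3. Standardize counts against independence: with row margins ``x(i)``, column
   margins ``y(j)`` and ``p(i,j) = x(i) y(j) / (L-1)^2``,

       M(i,j) = (M1(i,j) - (L-1) p(i,j)) / sqrt((L-1) p(i,j) (1 - p(i,j))).

4. Normalize every matrix to the common scale R^2 = sum m^2 = 110 n and
   K_d = sum m(i,j) p1(i) p2(j) = -1 with p1 = 1/n, p2 = 1/25, so that the
   alignment score distribution is comparable across matrices.

Because p1(i) p2(j) = 1/(25 n) is uniform, K_d is simply the cell mean, and
the unique orientation-preserving affine map hitting both targets is

    m' = a (m - mean),  then subtract 1,  with  a = sqrt(85 n / SS)

where SS is the sum of squared deviations from the mean.  The map is the
identity on matrices already satisfying both constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._rng import STREAM_MATRIX, substream
from .alphabet import GROUP_LETTERS
from .errors import DegenerateMatrixError, EmptyAlignmentError, NormalizationError

#: Target sum of squares per probe row after normalization.
R0_PER_ROW = 110.0
#: Target probability-weighted sum after normalization.
KD_TARGET = -1.0

#: Human-readable labels of the 25 pair categories, in column order
#: (column j for previous symbol p and current symbol c is (p-1) + 5(c-1)).
PAIR_LABELS = tuple(
    f"{GROUP_LETTERS[p]}>{GROUP_LETTERS[c]}" for c in range(5) for p in range(5)
)


@dataclass(frozen=True)
class PeriodicProbe:
    """The artificial cyclic sequence 1,2,...,n,1,2,... of length L."""

    n: int
    L: int
    symbols: np.ndarray  # int16, values 1..n

    def __len__(self) -> int:
        return self.L


def build_probe(n: int, L: int) -> PeriodicProbe:
    """Build the cyclic probe of consensus length ``n`` and total length ``L``."""
    if n < 2:
        raise ValueError(f"consensus length n must be >= 2, got {n}")
    if L < n:
        raise ValueError(f"probe length L must be >= n, got L={L}, n={n}")
    symbols = (np.arange(L, dtype=np.int64) % n + 1).astype(np.int16)
    return PeriodicProbe(n=n, L=L, symbols=symbols)


@dataclass(frozen=True)
class CountMatrix:
    """Adjacent-pair counts: n rows (probe positions) x 25 columns (pairs)."""

    n: int
    counts: np.ndarray  # (n, 25) int64

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def count_pairs(probe: PeriodicProbe, seq) -> CountMatrix:
    """Count adjacent symbol pairs of ``seq`` against the probe positions.

    For i = 2..L the pair (seq[i-1], seq[i]) is attributed to the probe row
    at position i.  The total equals L - 1.
    """
    symbols = np.asarray(seq.symbols if hasattr(seq, "symbols") else seq)
    if len(symbols) != probe.L:
        raise ValueError(
            f"sequence length {len(symbols)} != probe length {probe.L}"
        )
    counts = np.zeros((probe.n, 25), dtype=np.int64)
    if len(symbols) >= 2:
        rows = probe.symbols[1:].astype(np.int64) - 1
        cols = (symbols[:-1].astype(np.int64) - 1) + 5 * (
            symbols[1:].astype(np.int64) - 1
        )
        np.add.at(counts, (rows, cols), 1)
    return CountMatrix(n=probe.n, counts=counts)


def count_pairs_from_alignment(local) -> CountMatrix:
    """Count pairs along the aligned columns of a local alignment.

    Scanning the alignment left to right, a pair is recorded at column c when
    the column is a match (both probe and sequence symbols present) and the
    preceding column carries a sequence symbol; columns with a missing
    character on either side advance the scan without filling, so pairs are
    only counted within gap-free runs.  For a gapless alignment of length m
    the total is m - 1.
    """
    if local.aligned_pairs == 0:
        raise EmptyAlignmentError("cannot count pairs of an empty alignment")
    counts = np.zeros((local.n, 25), dtype=np.int64)
    ps = local.probe_symbols.astype(np.int64)
    ss = local.seq_symbols.astype(np.int64)
    if len(ps) >= 2:
        valid = (ps[1:] >= 1) & (ss[1:] >= 1) & (ss[:-1] >= 1)
        rows = ps[1:][valid] - 1
        cols = (ss[:-1][valid] - 1) + 5 * (ss[1:][valid] - 1)
        np.add.at(counts, (rows, cols), 1)
    return CountMatrix(n=local.n, counts=counts)


@dataclass(frozen=True)
class WeightMatrix:
    """Standardized pair-correlation weights (unnormalized scale)."""

    n: int
    matrix: np.ndarray  # (n, 25) float64


def weight_from_counts(m1: CountMatrix) -> WeightMatrix:
    """Convert counts to standardized weights (observed minus expected over
    the binomial standard deviation); cells with zero marginal probability
    carry no evidence and are set to 0."""
    counts = m1.counts.astype(np.float64)
    total = counts.sum()
    if total < 2:
        raise DegenerateMatrixError(f"need at least 2 counted pairs, got {total:g}")
    x = counts.sum(axis=1)
    y = counts.sum(axis=0)
    if np.count_nonzero(x) < 2 or np.count_nonzero(y) < 2:
        raise DegenerateMatrixError(
            "count matrix needs at least two non-zero rows and columns"
        )
    p = np.outer(x, y) / total**2
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(total * p * (1.0 - p))
        m = np.where(denom > 0, (counts - total * p) / denom, 0.0)
    return WeightMatrix(n=m1.n, matrix=m)


@dataclass(frozen=True)
class NormalizedWeightMatrix:
    """A weight matrix on the common scale R^2 = 110 n, K_d = -1."""

    n: int
    matrix: np.ndarray  # (n, 25) float64

    @property
    def r2(self) -> float:
        """Sum of squared elements."""
        return float((self.matrix**2).sum())

    @property
    def kd(self) -> float:
        """Probability-weighted sum with p1 = 1/n, p2 = 1/25 (the cell mean)."""
        return float(self.matrix.mean())


def normalize_matrix(m: WeightMatrix | NormalizedWeightMatrix) -> NormalizedWeightMatrix:
    """Affinely rescale a weight matrix to R^2 = 110 n and K_d = -1."""
    a = np.asarray(m.matrix, dtype=np.float64)
    n = m.n
    ss = float(((a - a.mean()) ** 2).sum())
    if ss <= 0.0:
        raise NormalizationError("constant matrix: normalization impossible")
    scale = np.sqrt(85.0 * n / ss)
    out = scale * (a - a.mean()) + KD_TARGET
    return NormalizedWeightMatrix(n=n, matrix=out)


@dataclass(frozen=True)
class MatrixSet:
    """The random matrix set Q(n) used to seed the iterative search."""

    n: int
    matrices: tuple[NormalizedWeightMatrix, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)


def random_normalized_matrix(n: int, rng: np.random.Generator) -> NormalizedWeightMatrix:
    """One member of Q(n): probe of length 1000 n counted against a uniform
    random 5-symbol sequence, standardized, then normalized."""
    L = 1000 * n
    probe = build_probe(n, L)
    s2 = rng.integers(1, 6, size=L, dtype=np.int8)
    m1 = count_pairs(probe, s2)
    return normalize_matrix(weight_from_counts(m1))


def generate_matrix_set(n: int, count: int = 1000, seed: int = 0) -> MatrixSet:
    """Generate Q(n): ``count`` independent random normalized matrices.

    Member i is drawn from its own RNG substream keyed by (n, i), so growing
    ``count`` extends the set without changing earlier members.
    """
    if n < 2:
        raise ValueError(f"consensus length n must be >= 2, got {n}")
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    matrices = tuple(
        random_normalized_matrix(n, substream(seed, STREAM_MATRIX, n, i))
        for i in range(count)
    )
    return MatrixSet(n=n, matrices=matrices, seed=seed)


# --- serialization ---------------------------------------------------------


def matrix_to_json(m: NormalizedWeightMatrix) -> str:
    return json.dumps({"n": m.n, "matrix": m.matrix.tolist()})


def matrix_from_json(text: str) -> NormalizedWeightMatrix:
    obj = json.loads(text)
    return NormalizedWeightMatrix(
        n=int(obj["n"]), matrix=np.asarray(obj["matrix"], dtype=np.float64)
    )


def matrix_to_tsv(m: NormalizedWeightMatrix) -> str:
    lines = ["pos\t" + "\t".join(PAIR_LABELS)]
    for i in range(m.n):
        lines.append(
            str(i + 1) + "\t" + "\t".join(repr(v) for v in m.matrix[i].tolist())
        )
    return "\n".join(lines) + "\n"
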