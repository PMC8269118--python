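"""Full repeat scan: iterative matrix refinement, Monte-Carlo significance,
period spectrum, overlap filtering and FDR estimation.

For one sequence and one candidate consensus length n the search proceeds as

1. For every matrix in the random set Q(n): align, recount pairs along the
   resulting local alignment, rebuild and renormalize the matrix, realign;
   accept while mF strictly increases, keep the best (mF, Local, MT) seen.
2. F_max(n) is the best refined mF over the whole set; its matrix is
   M_max(n) and its alignment Local(n).
3. Significance: the sequence is shuffled (default 200 times); each shuffle
   is refined starting from M_max(n) and its mF enters the null sample V_n;
   Z(n) = (F_max(n) - mean(V_n)) / sd(V_n).
4. Over the spectrum n = n_min..n_max, calls with Z >= Z0 are filtered
   greedily: keep the largest-Z call, drop every call whose alignment
   overlaps it by more than 50% of the shorter sequence-side span, repeat.

A repeat call must span at least 14 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import STREAM_SHUFFLE, substream
from .alphabet import RecodedSequence
from .cyclic_align import DEFAULT_DEL_PENALTY, LocalAlignment, local_align
from .divergence import divergence_degree, repeats_from_alignment
from .errors import (
    DegenerateMatrixError,
    DegenerateNullError,
    EmptyAfterFilterError,
    EmptyAlignmentError,
    NormalizationError,
    TooFewRepeatsError,
    TooShortError,
    UndefinedFDRError,
)
from .pwm import (
    MatrixSet,
    NormalizedWeightMatrix,
    PeriodicProbe,
    build_probe,
    count_pairs_from_alignment,
    generate_matrix_set,
    normalize_matrix,
    weight_from_counts,
)

DEFAULT_Z0 = 6.0
MIN_SPAN = 14

# Q(n) depends only on (n, set_size, seed); reuse across sequences of a run.
_Q_CACHE: dict[tuple[int, int, int], MatrixSet] = {}


def _cached_matrix_set(n: int, count: int, seed: int) -> MatrixSet:
    key = (n, count, seed)
    q = _Q_CACHE.get(key)
    if q is None:
        if len(_Q_CACHE) > 128:
            _Q_CACHE.clear()
        q = generate_matrix_set(n, count=count, seed=seed)
        _Q_CACHE[key] = q
    return q
#: Safety cap on refinement iterations; the loop normally exits much earlier
#: because each accepted iteration must strictly increase mF.
MAX_REFINE_ITER = 20


@dataclass
class SignificanceEstimate:
    """Monte-Carlo null summary for one consensus length."""

    mean: float
    variance: float
    shuffles: int
    z: float


@dataclass
class PeriodResult:
    """Best refined hit for one consensus length n."""

    n: int
    f_max: float
    m_max: NormalizedWeightMatrix
    local: LocalAlignment
    z: float | None = None
    significance: SignificanceEstimate | None = None


@dataclass
class TRAnnotation:
    """A filtered repeat call, with 1-based inclusive protein coordinates."""

    sequence_id: str
    n0: int
    l: int
    r: int
    z: float
    f_max: float
    m_max: NormalizedWeightMatrix
    alignment: LocalAlignment
    s: float | None = None  # divergence degree, filled by annotate_divergence


def refine_alignment(
    mt0: NormalizedWeightMatrix,
    probe: PeriodicProbe,
    seq,
    del_penalty: float = DEFAULT_DEL_PENALTY,
    max_iter: int = MAX_REFINE_ITER,
) -> tuple[float, LocalAlignment, NormalizedWeightMatrix]:
    """Iteratively refine a matrix against one sequence.

    Loop: align -> count pairs along Local -> standardize -> normalize ->
    realign, accepting only strict mF increases; stops on non-increase (which
    also rules out cyclic fluctuation) or when a rebuilt matrix is degenerate.
    Returns the best (mF, Local, MT) seen; an empty first alignment returns
    (0, empty Local, mt0).
    """
    best_local = local_align(mt0, probe, seq, del_penalty)
    best_mt = mt0
    best_score = best_local.score
    if best_local.is_empty:
        return 0.0, best_local, mt0
    cur_local = best_local
    for _ in range(max_iter):
        try:
            m1 = count_pairs_from_alignment(cur_local)
            mt = normalize_matrix(weight_from_counts(m1))
        except (DegenerateMatrixError, NormalizationError, EmptyAlignmentError):
            break
        cur_local = local_align(mt, probe, seq, del_penalty)
        if cur_local.score > best_score:
            best_score = cur_local.score
            best_local = cur_local
            best_mt = mt
        else:
            break
    return best_score, best_local, best_mt


def best_over_set(
    q: MatrixSet,
    probe: PeriodicProbe,
    seq,
    del_penalty: float = DEFAULT_DEL_PENALTY,
) -> PeriodResult:
    """Refine every matrix of Q(n); keep the argmax of refined mF
    (ties broken by member index)."""
    if len(q) == 0:
        raise ValueError("matrix set is empty")
    best: tuple[float, LocalAlignment, NormalizedWeightMatrix] | None = None
    for mt0 in q:
        score, local, mt = refine_alignment(mt0, probe, seq, del_penalty)
        if best is None or score > best[0]:
            best = (score, local, mt)
    return PeriodResult(n=q.n, f_max=best[0], m_max=best[2], local=best[1])


def significance_z(
    result: PeriodResult,
    seq,
    shuffles: int = 200,
    seed: int = 0,
    del_penalty: float = DEFAULT_DEL_PENALTY,
) -> SignificanceEstimate:
    """Monte-Carlo significance of F_max(n) against shuffled-sequence nulls.

    Each shuffle is realigned with the iterative refinement starting from
    M_max(n).  Z = (F_max - mean) / sd with the sample variance (ddof = 1).
    """
    if shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    symbols = np.asarray(seq.symbols if hasattr(seq, "symbols") else seq, dtype=np.int8)
    probe = build_probe(result.n, len(symbols))
    null = np.empty(shuffles, dtype=np.float64)
    for t in range(shuffles):
        rng = substream(seed, STREAM_SHUFFLE, result.n, t)
        shuffled = rng.permutation(symbols)
        null[t], _, _ = refine_alignment(
            result.m_max, probe, shuffled, del_penalty
        )
    mean = float(null.mean())
    var = float(null.var(ddof=1))
    if var <= 0.0:
        raise DegenerateNullError("null scores have zero variance")
    z = (result.f_max - mean) / np.sqrt(var)
    est = SignificanceEstimate(mean=mean, variance=var, shuffles=shuffles, z=float(z))
    result.z = est.z
    result.significance = est
    return est


def scan_sequence(
    seq: RecodedSequence,
    n_min: int = 2,
    n_max: int | None = None,
    set_size: int = 1000,
    shuffles: int = 200,
    seed: int = 0,
    del_penalty: float = DEFAULT_DEL_PENALTY,
) -> list[PeriodResult]:
    """Period spectrum: one refined, significance-scored result per n.

    ``n_max`` defaults to min(100, len(seq) // 2): a period longer than half
    the sequence cannot repeat twice.
    """
    L = len(seq)
    if L < MIN_SPAN:
        raise TooShortError(f"sequence of {L} symbols is shorter than {MIN_SPAN}")
    if n_max is None:
        n_max = min(100, L // 2)
    if n_min < 2:
        raise ValueError("n_min must be >= 2")
    if n_max < n_min:
        raise ValueError(f"empty period range [{n_min}, {n_max}]")
    if n_max > L:
        raise ValueError(f"n_max {n_max} exceeds sequence length {L}")
    spectrum: list[PeriodResult] = []
    for n in range(n_min, n_max + 1):
        q = _cached_matrix_set(n, set_size, seed)
        probe = build_probe(n, L)
        result = best_over_set(q, probe, seq, del_penalty)
        if result.local.is_empty:
            result.z = float("-inf")
        else:
            significance_z(result, seq, shuffles=shuffles, seed=seed,
                           del_penalty=del_penalty)
        spectrum.append(result)
    return spectrum


def _overlap_fraction(a: LocalAlignment, b: LocalAlignment) -> float:
    """Overlap of two sequence-side spans relative to the shorter one."""
    if a.is_empty or b.is_empty:
        return 0.0
    inter = min(a.seq_end, b.seq_end) - max(a.seq_start, b.seq_start) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a.seq_span, b.seq_span)


def filter_periods(
    spectrum: list[PeriodResult],
    z0: float = DEFAULT_Z0,
    seq: RecodedSequence | None = None,
    sequence_id: str = "",
) -> list[TRAnnotation]:
    """Greedy overlap filter over the period spectrum.

    Drops calls below Z0 or spanning fewer than 14 residues; repeatedly keeps
    the largest-Z remaining call and removes every call whose local alignment
    overlaps it by more than 50% of the shorter span (this removes the
    duplicate calls at 2n, 3n, ... of a true period).  When ``seq`` is given,
    reported boundaries are mapped onto the original protein (1-based,
    inclusive); otherwise they are recoded-sequence coordinates.
    """
    if not spectrum:
        raise ValueError("empty spectrum")
    live = [
        r for r in spectrum
        if r.z is not None and r.z >= z0 and r.local.seq_span >= MIN_SPAN
    ]
    annotations: list[TRAnnotation] = []
    while live:
        best = max(live, key=lambda r: (r.z, -r.n))
        l, r_ = best.local.seq_start, best.local.seq_end
        if seq is not None:
            l = int(seq.positions[l - 1]) + 1
            r_ = int(seq.positions[r_ - 1]) + 1
            sid = sequence_id or seq.id
        else:
            sid = sequence_id
        annotations.append(
            TRAnnotation(
                sequence_id=sid,
                n0=best.n,
                l=l,
                r=r_,
                z=best.z,
                f_max=best.f_max,
                m_max=best.m_max,
                alignment=best.local,
            )
        )
        live = [
            r for r in live
            if r is not best and _overlap_fraction(r.local, best.local) <= 0.5
        ]
    return annotations


def annotate_divergence(
    annotations: list[TRAnnotation],
    seq: RecodedSequence,
    symbol_space: str = "residues20",
) -> None:
    """Fill the divergence degree S of each annotation in place."""
    for ann in annotations:
        try:
            rma = repeats_from_alignment(ann.alignment, seq)
            ann.s = divergence_degree(rma, symbol_space=symbol_space).s
        except (TooFewRepeatsError, EmptyAfterFilterError):
            ann.s = None


def scan_protein(
    protein: str,
    sequence_id: str = "",
    n_min: int = 2,
    n_max: int | None = None,
    set_size: int = 1000,
    shuffles: int = 200,
    z0: float = DEFAULT_Z0,
    seed: int = 0,
    del_penalty: float = DEFAULT_DEL_PENALTY,
    symbol_space: str = "residues20",
) -> tuple[list[TRAnnotation], list[PeriodResult]]:
    """Convenience pipeline: recode, scan, filter, attach divergence."""
    from .alphabet import recode_sequence

    seq = recode_sequence(protein, id=sequence_id)
    spectrum = scan_sequence(
        seq, n_min=n_min, n_max=n_max, set_size=set_size,
        shuffles=shuffles, seed=seed, del_penalty=del_penalty,
    )
    annotations = filter_periods(spectrum, z0=z0, seq=seq, sequence_id=sequence_id)
    annotate_divergence(annotations, seq, symbol_space=symbol_space)
    return annotations, spectrum


def estimate_fdr(real_hits: int, shuffled_hits: int) -> float:
    """FDR = FP / (FP + TP): shuffled-set hit count over real-set hit count."""
    if real_hits == 0:
        raise UndefinedFDRError("no hits in the real set: FDR undefined")
    if shuffled_hits < 0 or real_hits < shuffled_hits:
        raise ValueError(
            f"need real_hits >= shuffled_hits >= 0, got {real_hits}, {shuffled_hits}"
        )
    return shuffled_hits / real_hits
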