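"""Artificial tandem-repeat benchmark generator and the correctness rule.

A benchmark sequence is built by (1) drawing a random repeat unit of length n
from the average Swiss-Prot residue composition (units made of a single
residue type — homo-repeats — are redrawn), (2) concatenating k copies,
(3) applying floor(i/100 * n k) substitution events at uniformly random
positions with replacement (a position may mutate repeatedly, and a
substitution may silently restore the original residue, which is what makes
substitution percentages above 100 meaningful), (4) applying indels at a rate
of 1 event per 100 residues, each an insertion or deletion of a single
residue with equal probability at a uniform position, and (5) inserting the
mutated array into a random position of a random flanking sequence (default
600 residues).  The true repeat boundaries (l0, r0) are recorded.

A detection is correct when some repeat call has exactly the planted
consensus length n and the called region overlaps the planted region by at
least 50% of its length; non-overlapping same-n calls have their overlap
lengths summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import STREAM_SIMULATE, substream

#: Average amino-acid composition of UniProtKB/Swiss-Prot (percent).  Used as
#: the default residue frequency table for random units and flanks; fully
#: overridable per spec.
SWISSPROT_COMPOSITION: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

DEFAULT_N_VALUES = (2, 5, 7, 10, 20, 40, 60, 80, 100)
DEFAULT_K_VALUES = (4, 8, 16, 24, 32, 50)
DEFAULT_FLANK = 600
DEFAULT_INDEL_RATE = 1.0  # events per 100 residues


@dataclass(frozen=True)
class ArtificialTRSpec:
    """Parameters of one artificial repeat-containing sequence."""

    n: int
    k: int
    substitution_percent: float = 0.0
    indel_rate: float = DEFAULT_INDEL_RATE  # events per 100 residues
    flank_length: int = DEFAULT_FLANK
    composition: dict[str, float] = field(default_factory=lambda: dict(SWISSPROT_COMPOSITION))
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.k < 2:
            raise ValueError("need n >= 2 and k >= 2")
        if self.substitution_percent < 0 or self.flank_length < 0 or self.indel_rate < 0:
            raise ValueError("substitution percent, indel rate and flank must be >= 0")


@dataclass(frozen=True)
class LabeledSequence:
    """A simulated sequence with ground-truth repeat boundaries (1-based)."""

    id: str
    sequence: str
    l0: int
    r0: int
    n: int
    spec: ArtificialTRSpec

    @property
    def tr_length(self) -> int:
        return self.r0 - self.l0 + 1


def _draw(rng: np.random.Generator, letters: np.ndarray, probs: np.ndarray, size: int) -> np.ndarray:
    return rng.choice(letters, size=size, p=probs)


def draw_repeat_unit(
    n: int, rng: np.random.Generator, composition: dict[str, float] | None = None
) -> np.ndarray:
    """A random n-residue unit from the composition table; units made of a
    single residue type (homo-repeats) are redrawn."""
    composition = composition or SWISSPROT_COMPOSITION
    letters = np.array(sorted(composition))
    probs = np.array([composition[a] for a in letters], dtype=np.float64)
    probs /= probs.sum()
    while True:
        unit = _draw(rng, letters, probs, n)
        if len(set(unit)) > 1:
            return unit


def make_artificial_tr_sequence(
    spec: ArtificialTRSpec,
    seed: int | None = None,
    id: str = "",
    unit: np.ndarray | None = None,
    _key=(),
) -> LabeledSequence:
    """Generate one labeled benchmark sequence (deterministic per spec+seed).

    ``unit`` allows the caller to reuse one random unit across several copy
    numbers, as the benchmark grid construction requires.
    """
    seed = spec.seed if seed is None else seed
    rng = substream(seed, STREAM_SIMULATE, *_key)
    letters = np.array(sorted(spec.composition))
    probs = np.array([spec.composition[a] for a in letters], dtype=np.float64)
    probs /= probs.sum()
    all_letters = letters  # substitutions draw uniformly over these

    if unit is None:
        unit = draw_repeat_unit(spec.n, rng, spec.composition)
    array = np.tile(unit, spec.k)

    # substitution events, positions with replacement, uniform target residue
    n_sub = int(np.floor(spec.substitution_percent / 100.0 * spec.n * spec.k))
    for _ in range(n_sub):
        pos = rng.integers(0, len(array))
        array[pos] = all_letters[rng.integers(0, len(all_letters))]

    # indel events: 1 per 100 residues, insertion or deletion with prob 1/2
    arr = list(array)
    n_indel = int(round(len(arr) * spec.indel_rate / 100.0))
    for _ in range(n_indel):
        if rng.random() < 0.5 and len(arr) > 2:
            del arr[rng.integers(0, len(arr))]
        else:
            pos = rng.integers(0, len(arr) + 1)
            arr.insert(pos, str(_draw(rng, letters, probs, 1)[0]))
    tr = "".join(arr)

    flank = "".join(_draw(rng, letters, probs, spec.flank_length))
    cut = int(rng.integers(0, spec.flank_length + 1))
    sequence = flank[:cut] + tr + flank[cut:]
    l0 = cut + 1
    r0 = cut + len(tr)
    return LabeledSequence(id=id, sequence=sequence, l0=l0, r0=r0, n=spec.n, spec=spec)


def make_benchmark_set(
    n_values=DEFAULT_N_VALUES,
    k_values=DEFAULT_K_VALUES,
    i: float = 0.0,
    units_per_n: int = 100,
    seed: int = 0,
    flank_length: int = DEFAULT_FLANK,
    indel_rate: float = DEFAULT_INDEL_RATE,
) -> list[LabeledSequence]:
    """The Cartesian benchmark W(i): for each n, ``units_per_n`` random units,
    each repeated at every copy number k (defaults give 9 x 100 x 6 = 5400)."""
    if not n_values or not k_values:
        raise ValueError("empty n or k grid")
    out: list[LabeledSequence] = []
    for n in n_values:
        for u in range(units_per_n):
            # one random unit per (n, u), shared by every copy number k
            unit = draw_repeat_unit(n, substream(seed, STREAM_SIMULATE, n, u))
            for k in k_values:
                spec = ArtificialTRSpec(
                    n=n, k=k, substitution_percent=i,
                    indel_rate=indel_rate, flank_length=flank_length, seed=seed,
                )
                out.append(
                    make_artificial_tr_sequence(
                        spec, id=f"W{i:g}_n{n}_k{k}_u{u}", unit=unit,
                        _key=(n, u, k, int(round(i * 10))),
                    )
                )
    return out


def shuffle_sequence(seq: str, seed: int = 0, tag: int = 0) -> str:
    """Uniform random permutation of the residues (composition preserved)."""
    rng = substream(seed, STREAM_SIMULATE, 999_999, tag)
    return "".join(rng.permutation(list(seq)))


def evaluate_detection(annotations, truth: LabeledSequence) -> bool:
    """The correctness rule: exact consensus length and >= 50% overlap of the
    planted region, summing non-overlapping same-n call spans."""
    covered = 0
    for ann in annotations:
        if ann.n0 != truth.n:
            continue
        inter = min(ann.r, truth.r0) - max(ann.l, truth.l0) + 1
        if inter > 0:
            covered += inter
    return covered >= 0.5 * truth.tr_length
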