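# Methods

## The detection problem

Tandem repeats (TRs) in proteins — consecutive approximate copies of a short
consensus unit — diverge quickly under evolution, accumulating substitutions
and indels until conventional similarity-based detectors no longer see them.
`divrep` implements a detector aimed precisely at this regime: repeats whose
divergence degree S exceeds 0.5 (fewer than half of the aligned residues
match their column consensus), provided enough copies are present.

Two modeling choices drive the sensitivity to divergent repeats:

1. **Reduced alphabet.** Residues are recoded into five physicochemical
   groups (non-polar **K** = G,A,V,I,L,P; polar **N** = S,T,C,M,Q,N; aromatic
   **I** = F,Y,W; positively charged **M** = K,R,H; negatively charged
   **T** = D,E).  Substitutions within a group — the common case in diverged
   repeats — become invisible.

2. **Pair-correlation scoring.** Alignment columns are scored by the ordered
   pair (previous symbol, current symbol), 25 categories over the 5-letter
   alphabet, so the score captures correlations between adjacent residues
   rather than single-position composition.

## The scan, step by step

For a sequence `Seq` of length `L` and each candidate consensus length
`n` (default 2..min(100, L/2)):

1. **Random matrix set Q(n).**  Each member is built by counting adjacent
   symbol pairs of a uniform random 5-symbol sequence of length `1000 n`
   against the cyclic probe `S1 = 1,2,...,n,1,2,...`, standardizing counts
   against independence,

       M(i,j) = (M1(i,j) − (L−1) p(i,j)) / sqrt((L−1) p(i,j) (1 − p(i,j))),
       p(i,j) = x(i) y(j) / (L−1)²,

   and normalizing to the common scale R² = Σ m² = 110 n, K_d = Σ m p1 p2 =
   −1 (p1 = 1/n, p2 = 1/25).  Because p1·p2 is uniform over cells, K_d is
   the cell mean and the normalization reduces to the closed-form affine map
   `m' = a (m − mean) − 1` with `a = sqrt(85 n / Σ(m − mean)²)`; it is
   exact, orientation-preserving, and the identity on already-normalized
   matrices.  Cells with zero marginal probability carry no evidence and are
   set to 0.  The default set size is 1000.

2. **Cyclic local alignment.**  `Seq` is aligned against a probe of length
   `L` under each matrix by a Smith–Waterman-style recurrence with linear
   indel penalty `del = 25.0`:

       F(i,j) = max{0, F(i−1,j−1) + MT(s1(j), t), F(i,j−1) − del, F(i−1,j) − del}

   where the pair category `t` is formed from the current sequence symbol
   and the symbol of the previous sequence position consumed on the best
   path into the diagonal predecessor.  Each cell stores that last-consumed
   symbol next to F; this makes the program a *heuristic* (a cell keeps one
   best state, whereas the true optimum over paths may require a dominated
   one).  In practice the heuristic is exact at small scale: on thousands of
   random instances (L ≤ 12) it matched exhaustive enumeration over the
   state space (i, j, last consumed position) without exception.  The first
   aligned column of a local path has no in-alignment predecessor and
   contributes 0, matching the pair-count convention.  Ties resolve match >
   gap-in-sequence > gap-in-probe, and among equal maxima the smallest
   (i, j); identical inputs therefore always give identical paths.

3. **Iterative refinement.**  Pairs are recounted along the resulting local
   alignment (a column is counted when it and its predecessor both carry a
   sequence symbol and the column has a probe symbol; gaps break the chain),
   the matrix is rebuilt and renormalized, and the sequence realigned.
   Iterations are accepted while mF strictly increases, which also rules out
   cyclic fluctuation; the best (mF, Local, MT) seen is kept.  F_max(n) is
   the maximum refined mF over Q(n); its matrix is M_max(n).

4. **Monte-Carlo significance.**  The sequence is shuffled (default 200
   times); each shuffle is refined starting from M_max(n) — not from the
   full Q(n) search, which would be three orders of magnitude more
   expensive and is unnecessary because M_max is fixed by the observed
   sequence.  With V the null scores,

       Z(n) = (F_max(n) − mean(V)) / sd(V),

   using the sample standard deviation.  The division is by the standard
   deviation, not the variance: Z is a standardized score and the threshold
   Z0 = 6 is on the sd scale.

5. **Overlap filtering.**  Calls with Z < Z0 (default 6.0) or spanning fewer
   than 14 residues are dropped.  Remaining calls are filtered greedily:
   keep the largest-Z call, remove every call whose sequence-side span
   overlaps it by more than 50% of the shorter span (the symmetric,
   strictest basis), repeat.  This removes the duplicate calls a true period
   n produces at 2n, 3n, and adjacent lengths.  A call overlapping exactly
   50% survives.

## Divergence degree

The sequence side of a filtered alignment is cut at probe-period boundaries
into a repeat multiple alignment (insertions against the probe become extra
columns, '.' marks gaps).  Columns with fewer than k/2 residues (strict; a
column holding exactly k/2 is retained) are disregarded; the per-column
modal symbol is the consensus, ties resolving to the fixed symbol order
(K,N,I,M,T for groups, alphabetical for residues); and

    S = 1 − v / v1

with v the consensus-matching residue count and v1 all retained residues.
S is reported in 20-letter residue space by default (recovered through the
recoding provenance); the 5-letter group space is available as an option,
since printed repeat alignments use group letters while the coincidence
matrix is defined over residue types.

## Matrix classification

Repeat matrices of a common n are compared by the cyclic Euclidean distance
B_min: the minimum over all n row rotations of the rooted sum of squared
differences (rooted, because the cut levels are on the Euclidean scale).
Complete-linkage agglomeration on pairwise B_min produces the class
dendrogram.  The cut B0 is chosen against element-shuffled twin matrices
(one per real matrix; shuffling preserves the value multiset and hence R²):
with X(B), Y(B) the mean class sizes of real and twin sets and r1, r2 the
class counts,

    Z_n(B) = (X(B) − Y(B)) / sqrt(D(X)/r1 + D(Y)/r2),

computed across classes at each cut (population variance), on a default grid
of 40 levels between the 1st and 99th percentiles of the real pairwise
distances; the smallest level with Z_n(B) > 10 is recommended.  Each class
is summarized by rotating members to the phase best matching the central
member (minimal summed within-class distance, ties to the smallest index)
and averaging cell-wise.

## The synthetic benchmark

The generator reproduces the artificial-repeat construction used to
characterize the method: a random unit of length n drawn from the average
Swiss-Prot residue composition (shipped as a fixed table; homo-repeat units
are redrawn; the same unit is reused across all copy numbers k of a grid),
repeated k times, mutated by floor(i/100 · nk) substitution events at
uniform positions *with replacement* — a position may mutate repeatedly and
a substitution may silently restore the original residue, which is what
makes substitution loads of 110–150% meaningful — plus indels at 1 event
per 100 residues (insertion or deletion of one residue with equal
probability, at a uniform position within the repeat array), embedded at a
uniform position inside a 600-residue random flank.  True boundaries
(l0, r0) are recorded after mutation.  A detection is correct when a call
has exactly the planted consensus length and same-length calls jointly cover
at least 50% of the planted region.

What the generator does *not* emulate: realistic substitution processes
(no rate matrices, no site heterogeneity), compositional bias of repeat
regions relative to the Swiss-Prot average, and correlated indels.  Passing
benchmarks therefore demonstrate recovery of planted periodicity under
uniform noise, not performance on any particular protein family.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| set_size | 1000 | random matrices per Q(n); more starts, better F_max |
| shuffles | 200 | Monte-Carlo null size; Z noise scales as 1/sqrt(2·shuffles) |
| z0 | 6.0 | significance threshold (sd units); ~34.5% FDR on shuffled databanks |
| del | 25.0 | linear indel penalty in alignment score units |
| n range | 2..min(100, L/2) | candidate consensus lengths; a period longer than L/2 cannot repeat |
| min span | 14 | minimum repeat-region size in residues |

## Numerical and design choices

- All randomness flows from one integer seed through named substreams keyed
  by (subsystem, n, member/shuffle index); results are independent of
  evaluation order and of how work would be scheduled across threads, and
  growing a set extends it without reshuffling earlier members.
- Scores are accumulated in float32 inside the alignment kernel (numba);
  score comparisons in the refinement loop require strict increase, so
  rounding cannot cause cycling.
- Degenerate situations fail loudly: constant matrices cannot be normalized,
  count matrices with fewer than two occupied rows or columns are rejected,
  a zero-variance Monte-Carlo null raises instead of returning an infinite Z.
- Non-standard residues (B, J, O, U, X, Z, '*') are skipped by default with
  positions recorded, preserving the local periodic phase; coordinates in
  all outputs refer to the original protein string (1-based, inclusive).
  A strict mode raises instead.

## Scaled-down evaluation sizes

Reported end-to-end numbers (the acceptance script, the heavier tests) use
reduced problem sizes chosen as desk-scale defaults: random-set size 100 and
50 shuffles per period; scan windows covering the planted periods ([5,9] for
the single high-divergence sequence, [5,10] for the benchmark grid); and 6
(script) or 2 (tests) random units per benchmark cell.  Per-sequence
operating parameters stay at the values above, so detection quality reflects
the method; replicate counts affect only sampling noise.

A caution on the benchmark detection-rate comparison: the published Table-1
style rates average a full 9×6 grid of (n, k) cells whose repeat-array sizes
nk span 8..5000, including many cells below the 14-residue minimum span
where no detector of this design can fire.  The desk-scale subset
(n ∈ {5,7,10}, k ∈ {16,32}, nk 80–320) sits in the method's favorable
regime and yields substantially higher rates (e.g. ~86% at 25%
substitutions against the published full-grid 59%).  The subset measures
the method's behavior in its intended operating region, not the full-grid
average; reproducing the latter would require the complete 5400-sequence
construction with scan range 2–100.

## Known limitations

- The refinement loop maximizes mF greedily per matrix; nothing guarantees a
  global optimum over matrices outside the random set.
- Scoring path-dependence (the stored last-consumed symbol) is inherited
  from the method; pathological matrices could in principle make the
  heuristic suboptimal, although none were found at small scale.
- Z estimates at reduced shuffle counts carry sampling error of order
  Z/sqrt(2·shuffles); ranking of well-separated periods is stable, marginal
  calls near Z0 are not.
- The scan is O(set_size · L²) per period; full-databank scans require the
  kind of cluster parallelism the work-unit seeding is designed to permit,
  but no parallel executor is shipped.
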