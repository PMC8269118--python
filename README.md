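# divrep

Detection of **highly divergent tandem repeats** in protein sequences.

Most repeat finders (T-REKS, XSTREAM, HHRepID, ...) excel at repeats whose
copies still resemble each other.  Repeats that have drifted past ~50%
divergence — more than half of the aligned residues no longer matching the
column consensus — are largely invisible to them, yet they shape protein
architecture (collagen-like arrays, α-helical heptads, β-sheet alternation,
solenoids).  `divrep` targets exactly that regime: given nothing but an
amino-acid sequence, it reports repeat regions with their consensus length
`n`, boundaries, Monte-Carlo significance `Z`, and divergence degree `S`.

## Method in brief

1. **Recoding.** Residues map to five physicochemical groups
   (K = GAVILP, N = STCMQN, I = FYW, M = KRH, T = DE), so within-group
   substitutions vanish.
2. **Cyclic pair-correlation alignment.** For each candidate period `n`, the
   sequence is locally aligned (Smith–Waterman with linear indel penalty
   `del = 25`) against the cyclic probe `1,2,…,n,1,2,…` under an `n × 25`
   weight matrix that scores the *pair* (previous symbol, current symbol) at
   each probe position:

   `F(i,j) = max{0, F(i−1,j−1) + MT(s1(j), t), F(i,j−1) − del, F(i−1,j) − del}`.

3. **Matrix refinement.** Starting from each member of a random set `Q(n)`
   of normalized matrices (`R² = 110 n`, `K_d = −1`), pair frequencies are
   recounted along the alignment, standardized
   (`M = (M1 − E)/sqrt(Var)`), renormalized and realigned while the score
   `mF` strictly increases.  The best refined score over the set is
   `F_max(n)` with matrix `M_max(n)`.
4. **Significance.** The sequence is shuffled (default 200×) and rescanned
   from `M_max(n)`; `Z(n) = (F_max(n) − mean) / sd` of the null scores.
   Calls need `Z ≥ Z0 = 6` (≈34.5% FDR on a shuffled databank) and a span of
   ≥ 14 residues; overlapping calls (harmonics `2n`, `3n`, near-lengths)
   are removed greedily by largest `Z`.
5. **Post-processing.** Each call's repeat copies form a multiple alignment
   from which the divergence degree `S = 1 − v/v1` is computed; repeat
   matrices of a common `n` can be clustered by cyclic Euclidean distance
   (complete linkage, randomization-calibrated cut) into consensus classes.

See `docs/methods.md` for the full model description, parameter table,
numerical conventions and limitations.

## Worked example

Simulate one sequence containing 30 copies of a random 7-residue unit,
mutated at 75% substitutions plus 1 indel per 100 residues, inside 600
residues of random flank — then scan it:

```
$ divrep simulate --n 7 --k 30 --subst 75 --units 1 --seed 42 --out bench
wrote 1 sequences

$ cat bench.truth.tsv
id      l0   r0   n  i   k   seed
W75_n7_k30_u0  529  736  7  75  30  42

$ divrep scan --fasta bench.fa --nmin 5 --nmax 10 \
      --set-size 50 --shuffles 40 --seed 7 --out hits
... INFO W75_n7_k30_u0: 1 repeat call(s) in 10.1s

$ cat hits.tsv
id      n0  l    r    Z       S       F_max
W75_n7_k30_u0  7   530  734  13.625  0.4878  450.820
```

The detector recovers the exact planted period (`n0 = 7`), boundaries
within one residue of the truth (530–734 vs. 529–736), a strongly
significant score (`Z = 13.6` standard deviations above the shuffled null)
and a divergence degree `S = 0.49` — i.e. barely half of the repeat
residues still match their column consensus, which is the regime this
detector exists for.  Scoring the call against the recorded truth:

```
$ divrep evaluate --annotations hits.tsv --truth bench.truth.tsv
n  i   detected  total  percent
7  75  1         1      100.0
```

The false-discovery-rate arithmetic used to calibrate `Z0`:

```
$ divrep fdr --real-hits 3720 --shuffled-hits 1284
FDR = 34.5%
```

Each hit also gets a JSON sidecar (`hits_hit0.json`) carrying the refined
weight matrix `M_max` and the alignment in 5-letter dot notation.  The same
functionality is available as a library (`divrep.scan_protein`,
`divrep.simulate`, `divrep.classify`, ...).

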