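# Methods

## Model and procedure

`starmsa` implements the center-star heuristic for multiple sequence
alignment of DNA. All k·(k−1)/2 pairs are aligned globally by
Needleman–Wunsch dynamic programming with integer scores and a linear
(per-symbol) gap cost. The pairwise optimum scores form a symmetric k×k
matrix; despite the conventional "distance matrix" name, entries are
similarity scores, so the center is the row with the *maximum* sum. Each
non-center sequence is then merged into the growing alignment through its
pairwise alignment against the center, under the once-a-gap-always-a-gap
rule: a gap newly introduced into the center is inserted at the same
column into every previously merged row and retained forever; a gap the
master already carries is propagated into the incoming row.

Assumptions: sequences are over {A, C, G, T}; the scoring is symmetric
(so the score matrix is symmetric and pair orientation does not matter);
gaps cost the same wherever they open (no affine model). The construction
is a heuristic — it does not optimise any whole-MSA objective, and its
output depends on the merge order only through gap placement, never
through pairwise content (the induced center/row projection of the final
MSA always equals the merged pairwise alignment exactly).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `match_reward` | +1 | score units | identical aligned pair |
| `mismatch_penalty` | −1 | score units | non-identical pair |
| `gap_penalty` | −2 | score units per gap symbol | linear; must be < 0 |
| `merge_order` | `input` | — | or `score` (best pairwise score vs center first) |

The default (+1, −1, −2) is the standard textbook DNA scheme; it
reproduces the shipped worked example's score matrix exactly and was
cross-validated against the exhaustive-enumeration oracle before being
frozen. Gap must be strictly negative or the boundary recurrence
degenerates; match must exceed mismatch or alignment is meaningless.

## Numerical and tie-break choices

- DP grid: (m+1)×(n+1) int64 NumPy array, row-major fill, 1-offset
  convention (`D[i][j]` scores prefixes `s[:i]`, `t[:j]`); boundary holds
  cumulative gap penalties. Interior cells carry a sentinel until filled;
  reading a score or traceback from an unfilled grid is a contract error.
- Traceback tie-break: diagonal, then vertical (gap in the second
  sequence), then horizontal. This makes every output bit-deterministic;
  among the two co-optimal layouts of the worked example's s1/s2 pair it
  selects `-CGCT` / `GCG-T`.
- Center ties resolve to the smallest index (first argmax).
- Merging walks the master center and the incoming gapped center in
  lockstep; when both show a gap at the cursor the gaps are matched
  greedily rather than stacked, which keeps merges of an already-seen
  alignment idempotent (no new master columns).
- Gap positions are logged as 0-based column indices in the evolving
  master alignment.
- Degenerate inputs: empty sequences and fewer than two sequences are
  rejected by the legality check; zero-length pair alignment is permitted
  at the DP level (single-cell grid, score 0). Duplicate sequences are
  allowed and simply tie.

## Synthetic data generator

`AncestorModel`/`generate_family` emulate a small family of related
sequences: a uniform-random ancestor (default 200 bases) mutated
independently into each descendant (default 4) by per-base substitutions
(default 5%) and indels (default 1% per base, insertion/deletion
equiprobable, length uniform in 1–3, inserted content uniform). Defaults
were chosen once as a realistic desk-scale stand-in for a handful of
closely related bacterial fragments of ~200 bases. The generator is
seeded and fully deterministic.

What it does *not* model: a phylogeny (all descendants are independent
draws from the ancestor, a star tree), rate heterogeneity, transition /
transversion bias, or real base composition. Passing tests therefore show
the aligner's correctness and invariants on family-like inputs, not its
biological alignment quality on real homologs.

## Verification strategy

Two independent routes check the pairwise core: an exhaustive recursive
enumeration of all global alignments (memoisation-free, sharing no code
with the DP, bounded at a combined length of 14), and Biopython's
`PairwiseAligner` configured with the same scheme. The merge rule is
checked against a hand-executed merge of the worked example (frozen as a
regression fixture) and against the induced-pairwise-consistency property
on randomized instances. Randomized batteries use fixed seeds: 200 pairs
for oracle agreement, 100 star instances (k ∈ [2,6], lengths ≤ 8) for the
structural invariants, sizes at which the exhaustive oracle is exact and
the whole suite runs in seconds.

## Limitations

- O(k²·L²) time and O(L²) memory per pair: fine for a handful of
  ~kilobase sequences, not for genome-scale input.
- One optimal alignment is reported per pair; co-optimal layouts are
  hidden behind the tie-break.
- No affine gaps, no local (Smith–Waterman) mode — the aligner-contract
  parameter of the distance-matrix builder leaves room to plug one in,
  but only the global mode ships.
- The center-star result carries no optimality guarantee for the MSA as
  a whole.
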