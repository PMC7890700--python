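# starmsa

Center-star multiple sequence alignment for small sets of DNA sequences,
built from small, independently testable components: a Needleman–Wunsch
global pairwise aligner, an all-pairs score matrix, center selection, and
an iterative merge under the *once a gap, always a gap* rule.

## Who it is for

Anyone who needs a transparent, exactly reproducible heuristic MSA of a
handful of related DNA sequences — for teaching, for testing other tools,
or as a reference implementation of the classic center-star construction.
It is not a competitor to production aligners on genome-scale data.

## The algorithm

Given sequences s₁ … s_k and an integer scoring scheme (match +1,
mismatch −1, linear gap −2 by default):

1. **Pairwise scores.** Every pair (sᵢ, sⱼ) is aligned globally by
   Needleman–Wunsch dynamic programming: with `D[i][j]` scoring the
   prefixes `s[:i]`, `t[:j]`,

   ```
   D[i][j] = max( D[i-1][j-1] + sub(s[i], t[j]),
                  D[i-1][j]   + gap,
                  D[i][j-1]   + gap )
   ```

   The optimal score fills a symmetric k×k matrix (diagonal unused).
2. **Center selection.** The sequence with the maximal row sum — the one
   most similar to all the others — becomes the center; ties go to the
   smallest index.
3. **Star merge.** Each remaining sequence is folded into the growing
   alignment via its cached pairwise alignment against the center. A gap
   inserted into the center during any merge is kept for the rest of the
   procedure and propagated into every other row (*leave blank once,
   leave blank everywhere*).

The result is a set of equal-width gapped rows, each degapping exactly to
its input. The construction is a fast heuristic, not an optimal MSA.

## Worked example

```python
from starmsa import build_distance_matrix, run_star, sum_rows, worked_example

seqs = worked_example()            # ["CGCT", "GCGT", "CCTG"]
dm = build_distance_matrix(seqs)
print(dm.dist)                     # [[ 0 -1 -1]
                                   #  [-1  0 -2]
                                   #  [-1 -2  0]]
print(sum_rows(dm))                # [-2, -3, -3]

result = run_star(seqs)
print(result.center_index)         # 0  (s1 has the best row sum)
for row in result.rows:
    print(row)                     # -CGCT-
                                   # GCG-T-
                                   # -C-CTG
```

The pairwise scores say s1 is closest to the other two (row sum −2 versus
−3 and −3), so s1 anchors the star. Merging s2 pushes a gap onto the front
of the center; merging s3 appends one at the end; both gaps appear in
every row of the final width-6 alignment.

The same run from the shell:

```sh
starmsa align --seqs CGCT GCGT CCTG
starmsa align --input seqs.fa --format aligned-fasta --out aligned.fa
starmsa generate --length 200 --n 4 --seed 42 --out family.fa
```

Short narrative scripts live in `examples/`.

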