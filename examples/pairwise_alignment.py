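"""Global pairwise alignment step by step.

Initialises the DP grid, fills it under the NW recurrence, and traces back
one optimal alignment, printing the grid so the boundary gap penalties and
the final (optimal) cell are visible.
"""

from starmsa import DEFAULT_SCHEME, fill_dp_matrix, init_dp_matrix, traceback

s, t = "CGCT", "GCGT"
matrix = fill_dp_matrix(init_dp_matrix(len(s), len(t)), s, t, DEFAULT_SCHEME)

print(f"DP grid for {s} vs {t} (match +1, mismatch -1, gap -2):")
print(matrix.scores)

pa = traceback(matrix, s, t, DEFAULT_SCHEME)
print(f"\noptimal score: {pa.score}  (bottom-right cell)")
print(f"  {pa.aligned_s}\n  {pa.aligned_t}")
print("One gap in each row: the -1 score is 3 matches + 2 gap penalties "
      "beating any gapless layout.")
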