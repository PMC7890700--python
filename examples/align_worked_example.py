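"""Align the built-in three-sequence demonstration set.

Builds the pairwise score matrix, picks the center, and prints the merged
alignment. The scores show why s1 wins: its summed score (-2) beats the
other rows (-3, -3).
"""

from starmsa import build_distance_matrix, run_star, sum_rows, worked_example

seqs = worked_example()
dm = build_distance_matrix(seqs)

print("pairwise score matrix (rows/cols s1..s3, diagonal unused):")
print(dm.dist)
print("row sums:", sum_rows(dm))

result = run_star(seqs)
print(f"\ncenter: s{result.center_index + 1}, alignment width {result.width}:")
for i, row in enumerate(result.rows):
    print(f"  s{i + 1}  {row}")

print("\nEach row degaps back to its input; gaps inserted into the center "
      "during one merge persist in every row (once a gap, always a gap).")
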