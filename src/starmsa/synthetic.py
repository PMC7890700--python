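"""Synthetic sequence families, the brute-force alignment oracle, and the
built-in worked example.

The generator emulates a small family of related DNA sequences: a random
ancestor mutated independently into each descendant by per-base
substitutions and short indels.  It is the desk-scale stand-in for the
kind of input the aligner targets (a handful of ~200-base bacterial
fragments); it makes no attempt at a realistic evolutionary model.

The brute-force scorer enumerates *all* global alignments recursively,
sharing no code with the DP implementation, and serves as the independent
oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairwise import DEFAULT_SCHEME, ScoringScheme

_BASES = "ACGT"

#: combined length bound above which exhaustive enumeration is refused
ORACLE_MAX_TOTAL_LEN = 14


@dataclass(frozen=True)
class AncestorModel:
    """Parameters of the ancestor/descendant generator.

    ``substitution_rate`` and ``indel_rate`` are per-base event
    probabilities; indels are insertions or deletions with equal
    probability and length uniform in ``[1, max_indel_len]``.  The same
    seed always yields the same family.
    """

    ancestor_length: int = 200
    n_descendants: int = 4
    substitution_rate: float = 0.05
    indel_rate: float = 0.01
    max_indel_len: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.ancestor_length <= 0 or self.n_descendants <= 0 or self.max_indel_len <= 0:
            raise ValueError("lengths and counts must be positive")
        for name in ("substitution_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")


def generate_family(model: AncestorModel) -> list[str]:
    """Draw a random ancestor and derive each descendant independently.

    Walking the ancestor left to right, each position first suffers an
    indel event with probability ``indel_rate`` (deletion skips the next
    L ancestral bases; insertion emits L uniform random bases), then the
    base is copied with a substitution to one of the three other bases
    with probability ``substitution_rate``.
    """
    rng = np.random.default_rng(model.seed)
    ancestor = "".join(rng.choice(list(_BASES), size=model.ancestor_length))
    family: list[str] = []
    for _ in range(model.n_descendants):
        out: list[str] = []
        i = 0
        while i < len(ancestor):
            if rng.random() < model.indel_rate:
                length = int(rng.integers(1, model.max_indel_len + 1))
                if rng.random() < 0.5:
                    i += length  # deletion
                    continue
                out.extend(rng.choice(list(_BASES), size=length))  # insertion
            base = ancestor[i]
            if rng.random() < model.substitution_rate:
                base = rng.choice([b for b in _BASES if b != base])
            out.append(base)
            i += 1
        family.append("".join(out))
    return family


def brute_force_score(
    s: str, t: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> int:
    """Maximum column score over an exhaustive enumeration of all global
    alignments of ``s`` and ``t``.

    Plain recursion over the three ways to consume the leading symbols
    (pair them, gap ``t``, gap ``s``); deliberately memoisation-free so it
    stays an independent implementation of the same objective, hence the
    tractability bound ``len(s) + len(t) <= 14``.
    """
    if len(s) + len(t) > ORACLE_MAX_TOTAL_LEN:
        raise ValueError(
            f"inputs too long for exhaustive enumeration "
            f"({len(s)} + {len(t)} > {ORACLE_MAX_TOTAL_LEN})"
        )

    def rec(i: int, j: int) -> int:
        if i == len(s) and j == len(t):
            return 0
        best = None
        if i < len(s) and j < len(t):
            best = scheme.substitution(s[i], t[j]) + rec(i + 1, j + 1)
        if i < len(s):
            cand = scheme.gap_penalty + rec(i + 1, j)
            best = cand if best is None else max(best, cand)
        if j < len(t):
            cand = scheme.gap_penalty + rec(i, j + 1)
            best = cand if best is None else max(best, cand)
        return best

    return rec(0, 0)


def worked_example() -> list[str]:
    """The built-in three-sequence demonstration set s1, s2, s3."""
    return ["CGCT", "GCGT", "CCTG"]
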