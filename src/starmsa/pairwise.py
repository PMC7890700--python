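"""Needleman-Wunsch global pairwise alignment.

The dynamic-programming core is split into independently testable steps --
matrix allocation/initialisation, fill, score extraction, traceback -- with
:func:`align` as the convenience composition.  Any callable with the
``align`` signature ``(s, t, scheme) -> PairwiseAlignment`` satisfies the
aligner contract expected by the distance-matrix builder, so alternative
alignment modes can be plugged in without touching the MSA layer.

Scores are integers throughout: a match reward, a mismatch penalty and a
linear (per-symbol) gap penalty.  The default scheme (+1, -1, -2) is the
unique common textbook scheme consistent with the worked three-sequence
example shipped in :mod:`starmsa.synthetic`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolationError, SequenceValidationError

logger = logging.getLogger(__name__)

GAP = "-"
ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class ScoringScheme:
    """Integer scoring for DNA global alignment with linear gap costs.

    Parameters
    ----------
    match_reward : int
        Score added for an identical aligned pair (default +1).
    mismatch_penalty : int
        Score added for a non-identical aligned pair (default -1).
    gap_penalty : int
        Score added per gap symbol in either row (default -2). Must be
        negative.
    """

    match_reward: int = 1
    mismatch_penalty: int = -1
    gap_penalty: int = -2

    def __post_init__(self) -> None:
        if self.match_reward <= self.mismatch_penalty:
            raise ValueError(
                "match_reward must exceed mismatch_penalty "
                f"(got {self.match_reward} <= {self.mismatch_penalty})"
            )
        if self.gap_penalty >= 0:
            raise ValueError(f"gap_penalty must be negative (got {self.gap_penalty})")

    def substitution(self, a: str, b: str) -> int:
        return self.match_reward if a == b else self.mismatch_penalty


DEFAULT_SCHEME = ScoringScheme()

# sentinel for interior cells between init and fill
_UNSET = np.iinfo(np.int64).min


@dataclass
class DpMatrix:
    """(m+1) x (n+1) integer score grid for global alignment.

    Cell ``[i][j]`` scores the prefixes ``s[:i]`` and ``t[:j]``; row 0 and
    column 0 hold cumulative gap penalties.  ``filled`` flips to True once
    the recurrence has been evaluated over the interior.
    """

    scores: np.ndarray
    m: int
    n: int
    filled: bool = field(default=False)


def init_dp_matrix(s_len: int, t_len: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> DpMatrix:
    """Allocate the DP grid and fill the boundary row/column.

    The boundary encodes the forced all-gap prefixes: ``scores[i][0] =
    i * gap_penalty`` and ``scores[0][j] = j * gap_penalty``.  Interior
    cells are left at a sentinel until :func:`fill_dp_matrix` runs.
    """
    if s_len < 0 or t_len < 0:
        raise ContractViolationError("sequence lengths must be non-negative")
    scores = np.full((s_len + 1, t_len + 1), _UNSET, dtype=np.int64)
    scores[:, 0] = scheme.gap_penalty * np.arange(s_len + 1)
    scores[0, :] = scheme.gap_penalty * np.arange(t_len + 1)
    return DpMatrix(scores=scores, m=s_len, n=t_len)


def fill_dp_matrix(
    matrix: DpMatrix, s: str, t: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> DpMatrix:
    """Evaluate the NW recurrence over the interior, row-major.

    Each cell takes the maximum of the diagonal move plus substitution
    score, the vertical move plus gap, and the horizontal move plus gap.
    The final cell then holds the optimal global alignment score.
    """
    if matrix.m != len(s) or matrix.n != len(t):
        raise ContractViolationError(
            f"matrix dimensions ({matrix.m}, {matrix.n}) do not match "
            f"sequence lengths ({len(s)}, {len(t)})"
        )
    sc = matrix.scores
    g = scheme.gap_penalty
    for i in range(1, matrix.m + 1):
        for j in range(1, matrix.n + 1):
            sub = sc[i - 1, j - 1] + scheme.substitution(s[i - 1], t[j - 1])
            up = sc[i - 1, j] + g
            left = sc[i, j - 1] + g
            sc[i, j] = max(sub, up, left)
    matrix.filled = True
    return matrix


def optimal_score(matrix: DpMatrix) -> int:
    """Return the last DP cell, the optimal global alignment score."""
    if not matrix.filled and (matrix.m > 0 and matrix.n > 0):
        raise ContractViolationError("DP matrix has not been filled")
    return int(matrix.scores[matrix.m, matrix.n])


@dataclass(frozen=True)
class PairwiseAlignment:
    """One optimal global alignment of two sequences.

    ``aligned_s`` and ``aligned_t`` are equal-length gapped texts;
    ``s_gap_cols``/``t_gap_cols`` list the 0-based columns holding a gap in
    the respective row.  No column is a gap in both rows.
    """

    score: int
    aligned_s: str
    aligned_t: str
    s_gap_cols: tuple[int, ...]
    t_gap_cols: tuple[int, ...]

    @property
    def width(self) -> int:
        return len(self.aligned_s)


def traceback(
    matrix: DpMatrix, s: str, t: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> PairwiseAlignment:
    """Recover one optimal alignment from a filled DP matrix.

    Ties are broken deterministically: diagonal first, then the vertical
    move (gap in ``t``), then the horizontal move (gap in ``s``).
    """
    if not matrix.filled and (matrix.m > 0 and matrix.n > 0):
        raise ContractViolationError("DP matrix has not been filled")
    if matrix.m != len(s) or matrix.n != len(t):
        raise ContractViolationError("matrix does not belong to these sequences")
    sc = matrix.scores
    g = scheme.gap_penalty
    i, j = matrix.m, matrix.n
    out_s: list[str] = []
    out_t: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and sc[i, j] == sc[i - 1, j - 1] + scheme.substitution(
            s[i - 1], t[j - 1]
        ):
            out_s.append(s[i - 1])
            out_t.append(t[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and sc[i, j] == sc[i - 1, j] + g:
            out_s.append(s[i - 1])
            out_t.append(GAP)
            i -= 1
        else:
            out_s.append(GAP)
            out_t.append(t[j - 1])
            j -= 1
    aligned_s = "".join(reversed(out_s))
    aligned_t = "".join(reversed(out_t))
    return PairwiseAlignment(
        score=optimal_score(matrix),
        aligned_s=aligned_s,
        aligned_t=aligned_t,
        s_gap_cols=tuple(k for k, c in enumerate(aligned_s) if c == GAP),
        t_gap_cols=tuple(k for k, c in enumerate(aligned_t) if c == GAP),
    )


def align(s: str, t: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Globally align two sequences: init, fill, traceback in one call."""
    for name, seq in (("s", s), ("t", t)):
        bad = set(seq) - ALPHABET
        if bad:
            raise SequenceValidationError(
                f"sequence {name} contains non-DNA symbols: {sorted(bad)}"
            )
    matrix = fill_dp_matrix(init_dp_matrix(len(s), len(t), scheme), s, t, scheme)
    return traceback(matrix, s, t, scheme)


def alignment_score(aligned_s: str, aligned_t: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Column-wise score of an existing alignment (consistency checks)."""
    if len(aligned_s) != len(aligned_t):
        raise ContractViolationError("aligned rows must have equal length")
    total = 0
    for a, b in zip(aligned_s, aligned_t):
        if a == GAP and b == GAP:
            raise ContractViolationError("column is a gap in both rows")
        if a == GAP or b == GAP:
            total += scheme.gap_penalty
        else:
            total += scheme.substitution(a, b)
    return total
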