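"""Component layer of the center-star aligner.

Five independently testable operations: sequence legality check, all-pairs
distance matrix, row sums, center selection, and the gap ledger that
implements the "leave blank once, leave blank everywhere" merging rule.

The "distance" matrix follows the field's (slightly misleading) naming: its
entries are optimal pairwise alignment *scores*, so larger means more
similar, and the center is the row with the *maximum* sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ContractViolationError, SequenceValidationError
from .pairwise import (
    DEFAULT_SCHEME,
    GAP,
    ALPHABET,
    PairwiseAlignment,
    ScoringScheme,
    align,
)

logger = logging.getLogger(__name__)

#: anything with the signature of :func:`starmsa.pairwise.align`
Aligner = Callable[[str, str, ScoringScheme], PairwiseAlignment]


def check_sequences(seqs: Sequence[str]) -> list[str]:
    """Validate and normalise a set of DNA sequences.

    At least two non-empty sequences over {A, C, G, T} are required.
    Lowercase input is upper-cased with a logged warning; any other symbol
    is rejected with its position.
    """
    if seqs is None or len(seqs) < 2:
        raise SequenceValidationError(
            f"too few sequences: need at least 2, got {0 if not seqs else len(seqs)}"
        )
    out: list[str] = []
    for idx, seq in enumerate(seqs):
        if not seq:
            raise SequenceValidationError(f"empty sequence at index {idx}")
        if seq != seq.upper():
            logger.warning("sequence %d contains lowercase bases; upper-casing", idx)
            seq = seq.upper()
        for pos, ch in enumerate(seq):
            if ch not in ALPHABET:
                raise SequenceValidationError(
                    f"invalid base {ch!r} at position {pos} of sequence {idx}"
                )
        out.append(seq)
    return out


@dataclass
class DistanceMatrix:
    """k x k symmetric matrix of pairwise alignment scores.

    The diagonal is unused and stored as 0; ``row_sums[i]`` is the sum of
    the off-diagonal entries of row ``i``.  ``alignments[(i, j)]`` (i < j)
    caches the traceback computed while scoring, for reuse by the merge
    phase.
    """

    dist: np.ndarray
    row_sums: np.ndarray
    n_seqs: int
    alignments: dict[tuple[int, int], PairwiseAlignment] = field(default_factory=dict)

    def get_alignment(self, i: int, j: int) -> PairwiseAlignment:
        """Cached alignment of sequences i and j, oriented as stored (i < j)."""
        key = (i, j) if i < j else (j, i)
        return self.alignments[key]


def build_distance_matrix(
    seqs: Sequence[str],
    aligner: Aligner = align,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> DistanceMatrix:
    """Align every pair once and mirror the scores into a symmetric matrix."""
    k = len(seqs)
    if k < 2:
        raise SequenceValidationError("too few sequences: need at least 2")
    dist = np.zeros((k, k), dtype=np.int64)
    cache: dict[tuple[int, int], PairwiseAlignment] = {}
    for i in range(k):
        for j in range(i + 1, k):
            pa = aligner(seqs[i], seqs[j], scheme)
            dist[i, j] = dist[j, i] = pa.score
            cache[(i, j)] = pa
    dm = DistanceMatrix(dist=dist, row_sums=np.zeros(k, dtype=np.int64), n_seqs=k,
                        alignments=cache)
    dm.row_sums = np.asarray(sum_rows(dm), dtype=np.int64)
    return dm


def sum_rows(dm: DistanceMatrix) -> list[int]:
    """Row sums of the distance matrix, diagonal excluded (it is stored 0)."""
    return [int(x) for x in dm.dist.sum(axis=1)]


@dataclass(frozen=True)
class CenterSelection:
    """Index of the chosen center sequence (maximum row sum, ties -> smallest)."""

    center_index: int


def select_center(dm: DistanceMatrix) -> CenterSelection:
    """Pick the sequence whose summed pairwise score is maximal."""
    if dm.n_seqs < 2:
        raise ContractViolationError("center selection needs at least 2 rows")
    # np.argmax returns the first maximum, i.e. the smallest index on ties
    return CenterSelection(center_index=int(np.argmax(dm.row_sums)))


@dataclass
class GapLedger:
    """Running record of the star merge under once-a-gap-always-a-gap.

    ``master_center`` is the center sequence with every gap inserted so
    far; ``rows`` are the already-merged sequences re-expressed in master
    coordinates (all the same length as the master); ``gap_log`` records,
    per merged sequence, the 0-based master-coordinate columns at which
    new center gaps were introduced during that merge.
    """

    center: str
    master_center: str = ""
    rows: list[str] = field(default_factory=list)
    gap_log: list[list[int]] = field(default_factory=list)
    merged_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.master_center:
            self.master_center = self.center


def merge_sequence(
    ledger: GapLedger, pa: PairwiseAlignment, seq_index: int | None = None
) -> GapLedger:
    """Fold one center-vs-sequence alignment into the ledger.

    ``pa.aligned_s`` must degap to the original (ungapped) center.  The
    two gapped views of the center -- the ledger's master and the incoming
    alignment's first row -- are walked in lockstep:

    * both show the same base: emit it, advance both;
    * both show a gap: match the gaps, the new row takes its own symbol;
    * only the master has a gap (from an earlier merge): the new row
      receives a gap there ("leave blank everywhere");
    * only the incoming alignment has a gap: a *new* column is inserted
      into the master and into every previously merged row.
    """
    if pa.aligned_s.replace(GAP, "") != ledger.center:
        raise ContractViolationError(
            "alignment's first row does not degap to the ledger's center sequence"
        )
    master = ledger.master_center
    new_master: list[str] = []
    new_row: list[str] = []
    inserted: list[int] = []  # master-coordinate columns new to this merge
    old_insert_at: list[int] = []  # positions in old-master coords to pad old rows
    i = j = 0
    while i < len(master) or j < len(pa.aligned_s):
        mc = master[i] if i < len(master) else None
        pc = pa.aligned_s[j] if j < len(pa.aligned_s) else None
        if mc is not None and pc is not None and mc != GAP and pc != GAP:
            # same center base seen through both views
            new_master.append(mc)
            new_row.append(pa.aligned_t[j])
            i += 1
            j += 1
        elif mc == GAP and pc == GAP:
            new_master.append(GAP)
            new_row.append(pa.aligned_t[j])
            i += 1
            j += 1
        elif mc == GAP:
            # gap from an earlier merge: propagate into the new row
            new_master.append(GAP)
            new_row.append(GAP)
            i += 1
        else:
            # new gap in the center: insert everywhere
            new_master.append(GAP)
            new_row.append(pa.aligned_t[j])
            inserted.append(len(new_master) - 1)
            old_insert_at.append(i)
            j += 1

    if old_insert_at:
        ledger.rows = [_insert_gaps(r, old_insert_at) for r in ledger.rows]
    ledger.master_center = "".join(new_master)
    ledger.rows.append("".join(new_row))
    ledger.gap_log.append(inserted)
    if seq_index is not None:
        ledger.merged_order.append(seq_index)
    return ledger


def _insert_gaps(row: str, positions: list[int]) -> str:
    """Insert a gap before each old-coordinate position (ascending order)."""
    out: list[str] = []
    prev = 0
    for p in positions:
        out.append(row[prev:p])
        out.append(GAP)
        prev = p
    out.append(row[prev:])
    return "".join(out)


@dataclass(frozen=True)
class StarMsaResult:
    """Final multiple alignment: equal-length gapped rows in input order."""

    rows: tuple[str, ...]
    center_index: int
    width: int


def finalize_msa(
    ledger: GapLedger, center_index: int, n_seqs: int
) -> StarMsaResult:
    """Reorder the ledger's rows back to original input order.

    The ledger holds the merged non-center rows in merge order plus the
    master center; the result interleaves them so ``rows[i]`` corresponds
    to input sequence ``i``.
    """
    if len(ledger.rows) != n_seqs - 1 or len(ledger.merged_order) != n_seqs - 1:
        raise ContractViolationError(
            f"ledger incomplete: {len(ledger.rows)} merged rows for {n_seqs} sequences"
        )
    width = len(ledger.master_center)
    ordered: list[str | None] = [None] * n_seqs
    ordered[center_index] = ledger.master_center
    for row, idx in zip(ledger.rows, ledger.merged_order):
        ordered[idx] = row
    if any(r is None or len(r) != width for r in ordered):
        raise ContractViolationError("ledger rows are inconsistent")
    return StarMsaResult(rows=tuple(ordered), center_index=center_index, width=width)
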