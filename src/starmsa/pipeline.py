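"""End-to-end center-star alignment.

Assembles the components in the canonical order: legality check, all-pairs
distance matrix, row sums, center selection, then one merge per non-center
sequence under the once-a-gap-always-a-gap rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .components import (
    GapLedger,
    StarMsaResult,
    build_distance_matrix,
    check_sequences,
    finalize_msa,
    merge_sequence,
    select_center,
)
from .pairwise import DEFAULT_SCHEME, PairwiseAlignment, ScoringScheme, align

logger = logging.getLogger(__name__)

MergeOrder = Literal["input", "score"]


@dataclass(frozen=True)
class StarConfig:
    """Pipeline configuration.

    ``merge_order`` decides the order in which non-center sequences join
    the alignment: ``input`` (original order, the default) or ``score``
    (descending pairwise score against the center, i.e. best first).
    """

    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    merge_order: MergeOrder = "input"
    output_format: Literal["aligned-fasta", "text"] = "text"


DEFAULT_CONFIG = StarConfig()


def run_star(seqs: Sequence[str], config: StarConfig = DEFAULT_CONFIG) -> StarMsaResult:
    """Run the full center-star pipeline on raw sequence texts.

    Pairwise tracebacks computed during distance-matrix construction are
    cached and reused in the merge phase, so each pair is aligned exactly
    once; the center is never aligned against itself.
    """
    validated = check_sequences(seqs)
    k = len(validated)
    dm = build_distance_matrix(validated, align, config.scheme)
    center = select_center(dm).center_index
    logger.info("k=%d center=%d row_sums=%s", k, center, list(dm.row_sums))

    others = [i for i in range(k) if i != center]
    if config.merge_order == "score":
        # best-scoring against the center first; index breaks ties
        others.sort(key=lambda i: (-int(dm.dist[center, i]), i))

    ledger = GapLedger(center=validated[center])
    for i in others:
        pa = _oriented(dm.get_alignment(center, i), center < i)
        merge_sequence(ledger, pa, seq_index=i)
    result = finalize_msa(ledger, center, k)
    logger.info("final width=%d", result.width)
    return result


def _oriented(pa: PairwiseAlignment, center_first: bool) -> PairwiseAlignment:
    """Return the cached alignment with the center as the first row."""
    if center_first:
        return pa
    return PairwiseAlignment(
        score=pa.score,
        aligned_s=pa.aligned_t,
        aligned_t=pa.aligned_s,
        s_gap_cols=pa.t_gap_cols,
        t_gap_cols=pa.s_gap_cols,
    )
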