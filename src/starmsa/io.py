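"""FASTA input and aligned output.

Reading goes through Biopython's SeqIO; writing wraps at 60 columns for
aligned FASTA or emits a plain-text block (one identifier-prefixed gapped
row per line) for quick terminal inspection.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

from .components import StarMsaResult
from .errors import SequenceValidationError

WRAP = 60


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA record: header text (without '>') and its sequence."""

    identifier: str
    sequence: str


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read all records from a FASTA file, in file order.

    Multi-line sequences are concatenated and CRLF endings tolerated
    (both handled by SeqIO).  Header-only records are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    records = [
        FastaRecord(identifier=rec.description or rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceValidationError(f"no FASTA records in {path}")
    for rec in records:
        if not rec.sequence:
            raise SequenceValidationError(f"empty sequence for record {rec.identifier!r}")
    return records


def write_alignment(
    result: StarMsaResult,
    records: Sequence[FastaRecord],
    fmt: str = "text",
    path: str | Path | None = None,
) -> None:
    """Write the final alignment as aligned FASTA or a plain-text block.

    ``records`` supplies the identifiers, in the same order as
    ``result.rows``; ``path=None`` writes to stdout.
    """
    if len(records) != len(result.rows):
        raise ValueError(
            f"{len(records)} records for {len(result.rows)} alignment rows"
        )
    if fmt not in ("aligned-fasta", "text"):
        raise ValueError(f"unknown output format: {fmt!r}")
    lines = (
        _fasta_lines(result.rows, records)
        if fmt == "aligned-fasta"
        else _text_lines(result.rows, records)
    )
    if path is None:
        _dump(lines, sys.stdout)
    else:
        with open(path, "w") as fh:
            _dump(lines, fh)


def _dump(lines: Iterable[str], fh: TextIO) -> None:
    for line in lines:
        fh.write(line + "\n")


def _fasta_lines(rows: Sequence[str], records: Sequence[FastaRecord]) -> Iterable[str]:
    for rec, row in zip(records, rows):
        yield f">{rec.identifier}"
        for start in range(0, len(row), WRAP):
            yield row[start : start + WRAP]


def _text_lines(rows: Sequence[str], records: Sequence[FastaRecord]) -> Iterable[str]:
    pad = max(len(r.identifier) for r in records)
    for rec, row in zip(records, rows):
        yield f"{rec.identifier:<{pad}}  {row}"
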