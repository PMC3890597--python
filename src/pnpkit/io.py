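"""Shared sequence records and readers/writers for the external formats.

The pipeline exchanges data as plain text: multi-record FASTA for sequences
and tab-separated tables for annotations (signal-peptide calls, protein
domain hits, BLAST tabular similarity hits, observed MS peptides, and
per-stage read counts). Lines starting with ``#`` in tables are comments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

NUCLEOTIDE_CHARS = frozenset("ACGTN")
# 20 standard amino acids plus X for ambiguity, * never stored in records
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_ALPHABETS = {NUCLEOTIDE: NUCLEOTIDE_CHARS, PROTEIN: PROTEIN_CHARS}


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    Sequences are stored upper-case; the identifier must be unique within a
    file and contain no whitespace.
    """

    identifier: str
    sequence: str
    alphabet: str = PROTEIN
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("sequence identifier must be non-empty")
        if any(c.isspace() for c in self.identifier):
            raise ValueError(f"identifier {self.identifier!r} contains whitespace")
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.identifier!r} has an empty sequence")
        allowed = _ALPHABETS[self.alphabet]
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.identifier!r}: character {ch!r} at position "
                    f"{pos} not allowed in {self.alphabet} alphabet"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


# Per-kind column schema: indices (0-based) that must parse as numbers.
TABLE_KINDS = {
    "signal_peptide": {"numeric": (1,), "ncols": 2},
    "domain_hit": {"numeric": (2, 3), "ncols": 4},
    "similarity_hit": {"numeric": (2, 3, 4, 5, 6, 7, 8, 9, 10, 11), "ncols": 12},
    "ms_peptide": {"numeric": (1, 2), "ncols": 3},
    "counts": {"numeric": None, "ncols": None},  # id + any number of numeric stages
}


@dataclass(frozen=True)
class AnnotationRow:
    """One row of an imported annotation table."""

    subject_id: str
    columns: tuple
    table_kind: str

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if self.table_kind not in TABLE_KINDS:
            raise ValueError(f"unknown table kind {self.table_kind!r}")


def read_fasta(path: str | os.PathLike, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; sequences are upper-cased with line breaks removed.
    An empty file yields an empty list. Duplicate identifiers and characters
    outside the declared alphabet raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        if bio_rec.id in seen:
            raise FormatError(f"duplicate identifier {bio_rec.id!r} in {path}")
        seen.add(bio_rec.id)
        desc = bio_rec.description
        if desc.startswith(bio_rec.id):
            desc = desc[len(bio_rec.id):].strip()
        try:
            records.append(
                SequenceRecord(bio_rec.id, str(bio_rec.seq), alphabet, desc)
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60
) -> None:
    """Write records as wrapped FASTA; ``read_fasta`` inverts this."""
    if width < 1:
        raise ValueError("width must be a positive integer")
    with open(path, "w") as handle:
        for rec in records:
            header = rec.identifier
            if rec.description:
                header += f" {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def _try_number(cell: str):
    try:
        value = float(cell)
    except ValueError:
        return None
    if value.is_integer() and "e" not in cell.lower() and "." not in cell:
        return int(value)
    return value


def _parse_row(cells: list[str], kind: str, lineno: int) -> AnnotationRow:
    schema = TABLE_KINDS[kind]
    numeric = schema["numeric"]
    if numeric is None:  # counts: everything after the id is numeric
        numeric = tuple(range(1, len(cells)))
    parsed: list = []
    for idx, cell in enumerate(cells):
        if idx in numeric:
            value = _try_number(cell)
            if value is None:
                raise FormatError(
                    f"line {lineno}: column {idx + 1} ({cell!r}) is not numeric "
                    f"for table kind {kind!r}"
                )
            parsed.append(value)
        else:
            parsed.append(cell)
    return AnnotationRow(cells[0], tuple(parsed), kind)


def _looks_like_header(cells: list[str], kind: str) -> bool:
    # a header has non-numeric text in EVERY numeric column; a data row with
    # one unparseable cell must still be reported as an error, not skipped
    schema = TABLE_KINDS[kind]
    numeric = schema["numeric"]
    if numeric is None:
        numeric = tuple(range(1, len(cells)))
    in_range = [idx for idx in numeric if idx < len(cells)]
    return bool(in_range) and all(_try_number(cells[idx]) is None for idx in in_range)


def read_table(path: str | os.PathLike, table_kind: str) -> list[AnnotationRow]:
    """Read a tab-separated annotation table.

    The first line may be a header (detected by non-numeric cells in numeric
    columns). ``similarity_hit`` expects the 12-column BLAST tabular dialect
    with query id, subject id and e-value in columns 1, 2 and 11. Ragged rows
    and unparseable numeric cells raise :class:`FormatError` with the line
    number. A header-only file yields an empty list.
    """
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    expected_ncols = TABLE_KINDS[table_kind]["ncols"]
    rows: list[AnnotationRow] = []
    width: int | None = expected_ncols
    first_data_line = True
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if first_data_line:
                first_data_line = False
                if width is None:
                    width = len(cells)
                if _looks_like_header(cells, table_kind):
                    if expected_ncols is not None and len(cells) != expected_ncols:
                        width = len(cells)
                    continue
            if width is not None and len(cells) != width:
                raise FormatError(
                    f"line {lineno}: expected {width} tab-separated columns, "
                    f"found {len(cells)}"
                )
            rows.append(_parse_row(cells, table_kind, lineno))
    return rows


def write_table(
    rows: Sequence[Sequence], path: str | os.PathLike, header: Sequence[str] | None = None
) -> None:
    """Write rows as TSV with an optional header line."""
    with open(path, "w") as handle:
        if header is not None:
            handle.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            handle.write("\t".join(map(str, row)) + "\n")


def to_biopython(rec: SequenceRecord) -> _BioSeqRecord:
    return _BioSeqRecord(Seq(rec.sequence), id=rec.identifier, description=rec.description)
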