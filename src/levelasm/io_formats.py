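"""FASTA/FASTQ input and level-labelled contig FASTA output.

Parsing is delegated to Bio.SeqIO; gzip-compressed files are handled
transparently by extension.  FASTQ quality strings are validated by the
parser but otherwise discarded — the assembly algorithm uses sequence
content only.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .records import ContigRecord, SequenceRecord

_WRAP = 60


class ParseError(ValueError):
    """Raised when an input file cannot be parsed in the named format."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read all records from a FASTA or FASTQ file.

    Sequences are upper-cased on read; record ids are the header token up
    to the first whitespace.  An empty file yields an empty list.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[SequenceRecord] = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, fmt):
                records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
        except ValueError as exc:
            raise ParseError(
                f"malformed {fmt} record near entry {len(records) + 1} "
                f"of {path}: {exc}"
            ) from exc
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> int:
    """Write plain FASTA (60-column wrap); returns the number written."""
    n = 0
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            _write_wrapped(out, rec.sequence)
            n += 1
    return n


def write_contigs(contigs: list[ContigRecord], path: str | Path) -> int:
    """Write contigs as FASTA with ``>{id}_{LEVEL}`` headers.

    Duplicate contig ids raise before anything is written.  Returns the
    number of records written; an empty contig list produces a valid empty
    file.
    """
    ids = [c.contig_id for c in contigs]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dupes}")
    with _open_text(path, "wt") as out:
        for contig in contigs:
            out.write(f">{contig.contig_id}_{contig.level_label}\n")
            _write_wrapped(out, contig.sequence)
    return len(contigs)


def write_fastq_pairs(pairs, prefix: str | Path) -> tuple[Path, Path]:
    """Write read pairs to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq`` with
    a constant dummy quality ('I')."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_1.fastq")
    p2 = prefix.with_name(prefix.name + "_2.fastq")
    with open(p1, "w") as h1, open(p2, "w") as h2:
        for pair in pairs:
            for handle, mate in ((h1, pair.mate1), (h2, pair.mate2)):
                handle.write(
                    f"@{mate.id}\n{mate.sequence}\n+\n{'I' * len(mate.sequence)}\n"
                )
    return p1, p2


def _write_wrapped(out, sequence: str) -> None:
    for i in range(0, len(sequence), _WRAP):
        out.write(sequence[i : i + _WRAP])
        out.write("\n")
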