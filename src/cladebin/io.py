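"""Standard-format I/O: FASTA, FASTQ, and tab-delimited tables.

Sequences are stored as plain Python strings. Identifiers are truncated at the
first whitespace character; original case is preserved on round trip and
uppercased only inside analysis code. FASTQ files are strict 4-line records.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_table",
    "write_table",
    "FastqParseError",
]


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 1-based line number of the fault."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Identifiers are truncated at the first whitespace.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(path: str | os.PathLike, records: dict[str, str], width: int = 60) -> None:
    """Write sequences as FASTA wrapped at `width` columns."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def _fastq_records(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    with open(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqParseError("expected '@' header", lineno)
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not seq or not plus or not qual:
                raise FastqParseError("truncated record", lineno)
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError("expected '+' separator", lineno - 1)
            seq, qual = seq.rstrip("\n"), qual.rstrip("\n")
            if len(seq) != len(qual):
                raise FastqParseError("sequence/quality length mismatch", lineno)
            name = header[1:].rstrip("\n").split()[0]
            yield name, seq, qual


def read_fastq(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTQ file into ``{id: sequence}`` (qualities are discarded)."""
    return {name: seq for name, seq, _ in _fastq_records(path)}


def write_fastq(
    path: str | os.PathLike,
    records: Iterable[tuple[str, str]],
    quality_char: str = "I",
) -> None:
    """Write 4-line FASTQ records with a constant quality string."""
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-delimited table with header row."""
    return pd.read_csv(path, sep="\t")


def write_table(path: str | os.PathLike, table: pd.DataFrame) -> None:
    """Write a tab-delimited table with header row, no index."""
    table.to_csv(path, sep="\t", index=False)
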