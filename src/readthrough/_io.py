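"""Sequence-file helpers: FASTA/FASTQ input (gzip transparent) via Biopython."""

from __future__ import annotations

import gzip
from typing import Iterator

from Bio import SeqIO


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def sniff_format(path: str) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            break
    raise ValueError(f"{path}: cannot determine sequence format (expected FASTA or FASTQ)")


def read_seqs(path: str) -> Iterator[tuple[str, str]]:
    """Yield (record id, uppercase sequence) from FASTA or FASTQ, .gz OK."""
    fmt = sniff_format(path)
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, fmt):
            yield record.id, str(record.seq).upper()


def write_fasta(path: str, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str, records: list[tuple[str, str]], qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")
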