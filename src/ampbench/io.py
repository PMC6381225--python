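"""FASTA/FASTQ input and output (gzip-aware by file suffix)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

PHRED_OFFSET = 33


def _open(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with _open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open(path, "r") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fastq(
    path: str | Path, records: Iterable[tuple[str, str, list[int]]]
) -> None:
    """Write 4-line FASTQ records given (id, sequence, phred qualities)."""
    with _open(path, "w") as fh:
        for name, seq, quals in records:
            if len(seq) != len(quals):
                raise ValueError(f"sequence/quality length mismatch for {name}")
            qstr = "".join(chr(q + PHRED_OFFSET) for q in quals)
            fh.write(f"@{name}\n{seq}\n+\n{qstr}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    with _open(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper(), list(
                rec.letter_annotations["phred_quality"]
            )
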