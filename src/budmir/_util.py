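"""Shared sequence and plain-text I/O helpers."""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from pathlib import Path

from Bio import SeqIO

DNA = "ACGT"

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement, DNA alphabet out (U treated as T)."""
    return seq.translate(_COMP)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and map U to T so RNA and DNA inputs compare equal."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs; sequences uppercased with U normalized to T."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, normalize_seq(str(rec.seq))


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) from a Sanger Phred+33 FASTQ."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq).upper(), qual


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def parse_collapsed_header(header: str) -> int:
    """Read count from a collapsed-FASTA header shaped like ``tag_12_x345``."""
    tail = header.rsplit("_x", 1)
    if len(tail) != 2 or not tail[1].isdigit():
        raise ValueError(f"not a collapsed-FASTA header: {header!r}")
    return int(tail[1])


def write_collapsed_fasta(path: str | Path, counts: dict[str, int]) -> None:
    """Write unique tags with counts encoded as ``>tag_<i>_x<count>`` headers."""
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(sorted(counts.items())):
            fh.write(f">tag_{i}_x{n}\n{seq}\n")


def read_collapsed_fasta(path: str | Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    for name, seq in read_fasta(path):
        counts[seq] = counts.get(seq, 0) + parse_collapsed_header(name)
    return counts
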