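"""FASTA/FASTQ input-output helpers.

Thin wrappers over Biopython's SeqIO so the rest of the package deals in
plain ``(id, sequence)`` tuples and ``(id, sequence, qualities)`` triples.
Files ending in ``.gz`` are transparently (de)compressed.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    with _open(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_fastq(path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (read_id, sequence, phred qualities) from a FASTQ file."""
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fastq(reads: Iterable[tuple[str, str, Iterable[int]]], path, offset: int = 33) -> None:
    """Write (read_id, sequence, qualities) triples as phred+33 FASTQ."""
    with _open(path, "wt") as fh:
        for rid, seq, quals in reads:
            qstr = "".join(chr(q + offset) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
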