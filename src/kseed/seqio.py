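"""Light FASTA/FASTQ plumbing shared by the pipeline modules.

Parsing goes through Biopython; records travel through the pipeline as a
small named tuple so simulation and mapping code does not pay SeqRecord
overhead per read.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


class FastqRecord(NamedTuple):
    id: str
    seq: str
    qual: str


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Yield FastqRecord tuples from a plain or gzipped FASTQ file."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield FastqRecord(rec.id, str(rec.seq).upper(), qual)


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> int:
    """Write FastqRecord tuples; returns the number written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
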