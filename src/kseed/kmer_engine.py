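"""Canonical k-mer counting over reads, with singleton filtering.

This is the genotyping substrate of the reference-free pipeline: every
accession's reads are reduced to the set of canonical 31-mers seen at least
twice, on the argument that k-mers observed once are dominated by sequencing
errors.  Counting is strand-neutral — each window is represented by the
lexicographic minimum of itself and its reverse complement — so it works on
whole-genome resequencing reads of unknown strand.

K-mers are stored internally as 2-bit-packed integer codes (A=0, C=1, G=2,
T=3, most significant base first), which makes numeric order identical to
lexicographic order on the underlying strings and lets the counting kernel
run vectorised in numpy.  The public surface speaks DNA strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from kseed.seqio import read_fastq, revcomp

DEFAULT_K = 31
MAX_K = 31  # 2 bits/base in a uint64 with headroom for shifts

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_BASES = "ACGT"


def encode_kmer(seq: str) -> int:
    """Pack an ACGT string into its 2-bit integer code."""
    code = 0
    for ch in seq:
        v = _CODE[ord(ch)]
        if v > 3:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {seq!r}")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def canonicalize_kmer(seq: str) -> str:
    """Return the canonical form: min(seq, revcomp(seq)) with A<C<G<T.

    Rejects non-ACGT characters; windows containing N are skipped upstream
    rather than canonicalized.  Idempotent by construction.
    """
    if any(_CODE[ord(c)] > 3 for c in seq):
        raise ValueError(f"non-ACGT character in k-mer {seq!r}")
    seq = seq.upper()
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def canonical_window_codes(seqs: Iterable[str], k: int) -> np.ndarray:
    """Canonical 2-bit codes of every ACGT-only length-k window of `seqs`.

    Windows touching a non-ACGT symbol are dropped entirely.  Returns an
    unsorted uint64 array with one entry per valid window (duplicates kept).
    """
    if not 3 <= k <= MAX_K:
        raise ValueError(f"k must be in [3, {MAX_K}], got {k}")
    blob = "N".join(seqs)
    if len(blob) < k:
        return np.empty(0, dtype=np.uint64)
    vals = _CODE[np.frombuffer(blob.encode("ascii"), dtype=np.uint8)]
    n_win = len(vals) - k + 1
    invalid = (vals > 3).astype(np.int64)
    bad = np.cumsum(invalid)
    window_bad = bad[k - 1 :].copy()
    window_bad[1:] -= bad[: n_win - 1]
    valid = window_bad == 0

    v = vals.astype(np.uint64)
    fwd = np.zeros(n_win, dtype=np.uint64)
    rc = np.zeros(n_win, dtype=np.uint64)
    comp = (np.uint64(3) - v) & np.uint64(3)  # junk where invalid; masked later
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | v[j : j + n_win]
        rc = (rc << np.uint64(2)) | comp[k - 1 - j : k - 1 - j + n_win]
    return np.minimum(fwd, rc)[valid]


@dataclass
class KmerCountTable:
    """Occurrence counts of canonical k-mers for one sample.

    `codes` is sorted ascending (equivalently: k-mers in lexicographic
    order); `counts` is aligned with it.
    """

    sample_id: str
    k: int
    codes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must align")
        if np.any(self.counts < 1):
            raise ValueError("all counts must be >= 1")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def total(self) -> int:
        """Total k-mer instances counted (sum of all counts)."""
        return int(self.counts.sum())

    def __contains__(self, kmer: str) -> bool:
        code = np.uint64(encode_kmer(canonicalize_kmer(kmer)))
        i = np.searchsorted(self.codes, code)
        return bool(i < len(self.codes) and self.codes[i] == code)

    def __getitem__(self, kmer: str) -> int:
        code = np.uint64(encode_kmer(canonicalize_kmer(kmer)))
        i = np.searchsorted(self.codes, code)
        if i < len(self.codes) and self.codes[i] == code:
            return int(self.counts[i])
        raise KeyError(kmer)

    def get(self, kmer: str, default: int = 0) -> int:
        try:
            return self[kmer]
        except KeyError:
            return default

    def items(self) -> Iterator[tuple[str, int]]:
        for code, count in zip(self.codes, self.counts):
            yield decode_kmer(int(code), self.k), int(count)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())


@dataclass
class SampleKmerSet:
    """Canonical k-mers of one accession surviving the min-count filter."""

    sample_id: str
    k: int
    codes: np.ndarray = field(repr=False)
    n_raw: int = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, kmer: str) -> bool:
        code = np.uint64(encode_kmer(canonicalize_kmer(kmer)))
        i = np.searchsorted(self.codes, code)
        return bool(i < len(self.codes) and self.codes[i] == code)

    def kmers(self) -> Iterator[str]:
        for code in self.codes:
            yield decode_kmer(int(code), self.k)

    def to_set(self) -> set[str]:
        return set(self.kmers())


def count_canonical_kmers(
    reads: Iterable[str] | str | Path,
    k: int = DEFAULT_K,
    sample_id: str = "sample",
) -> KmerCountTable:
    """Count canonical k-mers over reads.

    `reads` may be an iterable of sequence strings or a path to a FASTQ file
    (plain or gzipped).  Every ACGT-only window of length k contributes one
    count to its canonical key; windows containing other symbols are skipped.
    Empty input yields an empty table.
    """
    if isinstance(reads, (str, Path)) and Path(reads).exists():
        seqs: Iterable[str] = (rec.seq for rec in read_fastq(reads))
    elif isinstance(reads, (str, Path)):
        raise FileNotFoundError(reads)
    else:
        seqs = reads
    window_codes = canonical_window_codes(seqs, k)
    codes, counts = np.unique(window_codes, return_counts=True)
    return KmerCountTable(sample_id=sample_id, k=k, codes=codes, counts=counts)


def filter_min_count(table: KmerCountTable, min_count: int = 2) -> SampleKmerSet:
    """Drop k-mers seen fewer than `min_count` times (default: singletons).

    Singletons are filtered because a k-mer observed once in shotgun data is
    most plausibly a sequencing error; `min_count=1` is the identity.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    keep = table.counts >= min_count
    return SampleKmerSet(
        sample_id=table.sample_id,
        k=table.k,
        codes=table.codes[keep],
        n_raw=table.total,
    )


def kmer_set_of_sequence(seq: str, k: int = DEFAULT_K) -> set[str]:
    """Canonical k-mer set of a sequence (brute-force-friendly reference)."""
    codes = np.unique(canonical_window_codes([seq], k))
    return {decode_kmer(int(c), k) for c in codes}


def sequence_kmer_codes(seq: str | Iterable[str], k: int = DEFAULT_K) -> np.ndarray:
    """Sorted unique canonical codes of a sequence (or sequences)."""
    seqs = [seq] if isinstance(seq, str) else list(seq)
    return np.unique(canonical_window_codes(seqs, k))


def write_kmer_table(table: KmerCountTable, path: str | Path) -> None:
    """Write `kmer<TAB>count`, k-mers in lexicographic order."""
    with open(path, "w") as fh:
        fh.write(f"#sample={table.sample_id}\tk={table.k}\tn_raw={table.total}\n")
        for kmer, count in table.items():
            fh.write(f"{kmer}\t{count}\n")


def read_kmer_table(path: str | Path) -> KmerCountTable:
    sample_id, k = Path(path).stem, None
    codes, counts = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                meta = dict(f.split("=", 1) for f in line[1:].split("\t") if "=" in f)
                sample_id = meta.get("sample", sample_id)
                k = int(meta["k"]) if "k" in meta else k
                continue
            kmer, count = line.split("\t")
            if k is None:
                k = len(kmer)
            codes.append(encode_kmer(kmer))
            counts.append(int(count))
    order = np.argsort(np.asarray(codes, dtype=np.uint64))
    return KmerCountTable(
        sample_id=sample_id,
        k=k or DEFAULT_K,
        codes=np.asarray(codes, dtype=np.uint64)[order],
        counts=np.asarray(counts, dtype=np.int64)[order],
    )
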