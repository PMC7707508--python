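"""mRNA and small-RNA evidence for a chimeric, hairpin-bearing transcript.

Three lines of evidence support the chimeric-gene / mirtron model and each
has a dedicated operation here:

* splice-junction quantification — reads matching the concatenation of one
  exon's suffix and the next exon's prefix count toward that junction, and
  a junction is "supported" at a minimum coverage of 5 spanning reads;
* exon/intron partitioning of exact-mapped small RNAs over gene models —
  a gene whose intron carries substantial small-RNA depth while paralogs'
  introns carry none is the mirtron signature;
* perfect-match coverage between paralogs — how much of a distant paralog
  could be explained by exact shared blocks of at least 20 bp, the
  alternative hypothesis to amplification via phased secondary siRNAs.

Small-RNA handling is deliberately exact: adapters are found by a k-mer
probe heuristic and trimmed reads are mapped with zero mismatches, every
occurrence on either strand reported (hairpin-arm multi-mapping is the
phenomenon of interest, not a nuisance).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from kseed.seqio import FastqRecord, revcomp

DEFAULT_MIN_LEN = 14
DEFAULT_MAX_LEN = 43
DEFAULT_MIN_JUNCTION_COVERAGE = 5


@dataclass
class GeneModel:
    """A gene as ordered exon intervals (0-based half-open) on one contig."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be disjoint")
        for s, e in exons:
            if e <= s:
                raise ValueError("empty exon interval")
        self.exons = exons

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def junctions(self) -> list[tuple[int, int]]:
        """(donor_end, acceptor_start) genomic pairs between consecutive exons."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def transcript_sequence(self, ref_seq: str) -> str:
        """Spliced transcript (exons concatenated; minus-strand genes revcomped)."""
        spliced = "".join(ref_seq[s:e] for s, e in self.exons)
        return revcomp(spliced) if self.strand == "-" else spliced


def read_gff3_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene + exon features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [
            (exon.start - 1, exon.end)  # GFF3 is 1-based inclusive
            for exon in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            continue
        models.append(
            GeneModel(gene_id=gene.id, contig=gene.seqid, strand=gene.strand, exons=exons)
        )
    return models


@dataclass
class AdapterCall:
    adapter: str
    support: int  # reads containing the adapter
    fraction: float  # support / total reads


def detect_adapter(
    reads: Sequence[FastqRecord],
    reference_seqs: Mapping[str, str],
    probe_len: int = 12,
    min_frac: float = 0.2,
) -> AdapterCall | None:
    """Find the 3' adapter as the dominant reference-absent probe k-mer.

    The candidate is the most frequent ``probe_len``-mer across all read
    windows that never occurs in the reference (either strand); it must be
    carried by at least ``min_frac`` of reads, and is extended greedily
    rightward while the extension keeps that support.  Returns None when no
    candidate clears the support bar.
    """
    if not reads:
        raise ValueError("no reads supplied")
    ref_probes: set[str] = set()
    for seq in reference_seqs.values():
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - probe_len + 1):
                ref_probes.add(strand_seq[i : i + probe_len])

    window_counts: Counter[str] = Counter()
    for rec in reads:
        for i in range(len(rec.seq) - probe_len + 1):
            window_counts[rec.seq[i : i + probe_len]] += 1

    def support(probe: str) -> int:
        return sum(1 for rec in reads if probe in rec.seq)

    candidate = None
    for probe, _ in window_counts.most_common():
        if probe not in ref_probes:
            candidate = probe
            break
    if candidate is None:
        return None
    n_reads = len(reads)
    cand_support = support(candidate)
    if cand_support < min_frac * n_reads:
        return None

    # greedy rightward extension while support holds
    adapter = candidate
    while True:
        votes: Counter[str] = Counter()
        for rec in reads:
            i = rec.seq.find(adapter)
            if i != -1 and i + len(adapter) < len(rec.seq):
                votes[rec.seq[i + len(adapter)]] += 1
        if not votes:
            break
        base, _ = votes.most_common(1)[0]
        extended = adapter + base
        ext_support = support(extended)
        if ext_support < min_frac * n_reads:
            break
        adapter, cand_support = extended, ext_support
    return AdapterCall(adapter=adapter, support=cand_support, fraction=cand_support / n_reads)


def trim_adapter(
    reads: Iterable[FastqRecord],
    adapter: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[FastqRecord], dict[str, int]]:
    """Cut each read at the first occurrence of the adapter's leading 8-mer.

    Trimmed reads outside [min_len, max_len] are discarded; counts of kept /
    too-short / too-long reads are returned alongside the surviving records.
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    probe = adapter[:8]
    kept: list[FastqRecord] = []
    stats = {"kept": 0, "too_short": 0, "too_long": 0}
    for rec in reads:
        cut = rec.seq.find(probe)
        seq = rec.seq[:cut] if cut != -1 else rec.seq
        if len(seq) < min_len:
            stats["too_short"] += 1
        elif len(seq) > max_len:
            stats["too_long"] += 1
        else:
            kept.append(FastqRecord(rec.id, seq, rec.qual[: len(seq)]))
            stats["kept"] += 1
    return kept, stats


@dataclass(frozen=True)
class Alignment:
    read_id: str
    contig: str
    start: int  # 0-based
    length: int
    strand: str

    @property
    def end(self) -> int:
        return self.start + self.length


def map_reads_exact(
    reads: Sequence[FastqRecord], reference_seqs: Mapping[str, str]
) -> tuple[list[Alignment], list[str]]:
    """Exact-occurrence mapping, zero mismatches, all hits on both strands.

    Returns (alignments, unmapped read ids).  A read matching several
    places — e.g. both arms of a near-perfect inverted repeat — reports
    every occurrence rather than being assigned to one.
    """

    def occurrences(hay: str, needle: str) -> list[int]:
        out, i = [], hay.find(needle)
        while i != -1:
            out.append(i)
            i = hay.find(needle, i + 1)
        return out

    hit_cache: dict[str, list[tuple[str, int, str]]] = {}
    alignments: list[Alignment] = []
    unmapped: list[str] = []
    for rec in reads:
        if rec.seq not in hit_cache:
            hits = []
            rc = revcomp(rec.seq)
            for contig, seq in reference_seqs.items():
                hits.extend((contig, i, "+") for i in occurrences(seq, rec.seq))
                hits.extend((contig, i, "-") for i in occurrences(seq, rc))
                if rc == rec.seq:  # palindromic read: strands coincide
                    hits = [h for h in hits if h[2] == "+"]
            hit_cache[rec.seq] = hits
        hits = hit_cache[rec.seq]
        if not hits:
            unmapped.append(rec.id)
        alignments.extend(
            Alignment(rec.id, contig, start, len(rec.seq), strand)
            for contig, start, strand in hits
        )
    return alignments, unmapped


@dataclass
class JunctionCount:
    donor_end: int  # genomic end of the upstream exon (0-based half-open)
    acceptor_start: int  # genomic start of the downstream exon
    count: int
    min_coverage: int = DEFAULT_MIN_JUNCTION_COVERAGE

    @property
    def passes_min(self) -> bool:
        return self.count >= self.min_coverage


def count_junction_reads(
    reads: Sequence[FastqRecord],
    ref_seq: str,
    gene: GeneModel,
    anchor: int = 8,
    min_coverage: int = DEFAULT_MIN_JUNCTION_COVERAGE,
) -> list[JunctionCount]:
    """Count reads spanning each splice junction of a gene model.

    A read spans a junction when it matches the spliced transcript exactly
    (either strand) across the exon boundary with at least ``anchor`` bases
    on each side.  A read is counted at most once per junction.
    """
    if reads and anchor > min(len(r.seq) for r in reads):
        raise ValueError("anchor exceeds the shortest read length")
    spliced = "".join(ref_seq[s:e] for s, e in gene.exons)
    boundaries = list(np.cumsum([e - s for s, e in gene.exons[:-1]]))
    counts = [0] * len(boundaries)
    for rec in reads:
        spanned: set[int] = set()
        for query in (rec.seq, revcomp(rec.seq)):
            start = spliced.find(query)
            while start != -1:
                end = start + len(query)
                for j, b in enumerate(boundaries):
                    if start <= b - anchor and end >= b + anchor:
                        spanned.add(j)
                start = spliced.find(query, start + 1)
            if rec.seq == revcomp(rec.seq):
                break
        for j in spanned:
            counts[j] += 1
    return [
        JunctionCount(donor_end=d, acceptor_start=a, count=c, min_coverage=min_coverage)
        for (d, a), c in zip(gene.junctions(), counts)
    ]


@dataclass
class SmallRnaProfile:
    """Per-position small-RNA depth over a gene span with exon/intron split.

    Depth is read-base depth: every aligned base of every read inside the
    gene span increments its position.  A read counts as intronic (exonic)
    only when fully inside one intron (exon); reads straddling a boundary
    are tallied separately and excluded from the intronic fraction.
    """

    gene_id: str
    span: tuple[int, int]
    depth: np.ndarray = field(repr=False)
    exon_reads: int = 0
    intron_reads: int = 0
    straddle_reads: int = 0

    @property
    def intronic_fraction(self) -> float:
        total = self.exon_reads + self.intron_reads
        return self.intron_reads / total if total else 0.0


def profile_small_rna(
    alignments: Sequence[Alignment], gene: GeneModel
) -> SmallRnaProfile:
    """Partition exact small-RNA alignments over one gene model."""
    start, end = gene.span
    depth = np.zeros(end - start, dtype=np.int64)
    exon_reads = intron_reads = straddle_reads = 0
    for aln in alignments:
        if aln.contig != gene.contig or aln.end <= start or aln.start >= end:
            continue
        lo, hi = max(aln.start, start), min(aln.end, end)
        depth[lo - start : hi - start] += 1
        if aln.start < start or aln.end > end:
            straddle_reads += 1
        elif any(s <= aln.start and aln.end <= e for s, e in gene.exons):
            exon_reads += 1
        elif any(s <= aln.start and aln.end <= e for s, e in gene.introns):
            intron_reads += 1
        else:
            straddle_reads += 1
    return SmallRnaProfile(
        gene_id=gene.gene_id,
        span=(start, end),
        depth=depth,
        exon_reads=exon_reads,
        intron_reads=intron_reads,
        straddle_reads=straddle_reads,
    )


@dataclass
class ParalogMatchReport:
    """How much of a subject paralog is covered by exact shared blocks."""

    query_id: str
    subject_id: str
    min_len: int
    covered_intervals: list[tuple[int, int]]
    subject_len: int

    @property
    def covered_bp(self) -> int:
        return sum(e - s for s, e in self.covered_intervals)

    @property
    def fraction(self) -> float:
        return self.covered_bp / self.subject_len


def paralog_perfect_match_coverage(
    seq_a: str,
    seq_b: str,
    min_len: int = 20,
    query_id: str = "query",
    subject_id: str = "subject",
) -> ParalogMatchReport:
    """Fraction of ``seq_b`` covered by exact matches >= min_len to ``seq_a``.

    Both orientations of ``seq_a`` are considered.  A position of ``seq_b``
    is covered iff it lies in some shared exact block of at least
    ``min_len`` bases, which is equivalent to lying in a length-``min_len``
    window shared verbatim with ``seq_a`` — so coverage is computed from
    shared seed windows and merged into maximal intervals.
    """
    if min(len(seq_a), len(seq_b)) < min_len:
        raise ValueError("both sequences must be at least min_len long")
    seeds: set[str] = set()
    for strand_seq in (seq_a, revcomp(seq_a)):
        for i in range(len(strand_seq) - min_len + 1):
            seeds.add(strand_seq[i : i + min_len])
    covered = np.zeros(len(seq_b), dtype=bool)
    for i in range(len(seq_b) - min_len + 1):
        if seq_b[i : i + min_len] in seeds:
            covered[i : i + min_len] = True
    intervals: list[tuple[int, int]] = []
    run_start = None
    for i, c in enumerate(covered):
        if c and run_start is None:
            run_start = i
        elif not c and run_start is not None:
            intervals.append((run_start, i))
            run_start = None
    if run_start is not None:
        intervals.append((run_start, len(seq_b)))
    return ParalogMatchReport(
        query_id=query_id,
        subject_id=subject_id,
        min_len=min_len,
        covered_intervals=intervals,
        subject_len=len(seq_b),
    )
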