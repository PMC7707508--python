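"""Anchor significant k-mers on references; k-mer-vs-VCF genotype concordance.

A 31-mer that is strongly associated with a phenotype but has no exact
occurrence in any supplied reference assembly is the signature of a
structural breakpoint missing from the assembly — the situation this module
classifies.  Exact canonical-31-mer lookup replaces alignment-based
localization: a hit means the reference contains the k-mer verbatim on
either strand.

The second half reconciles the reference-free and reference-based worlds:
for each biallelic SNP site it derives the ref- and alt-carrying k-mers,
calls genotypes from their presence in a sample's k-mer set, and scores
concordance against reference-based calls.  Het calling from joint
presence of both allele k-mer sets extends pure presence/absence logic and
is stated explicitly in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from kseed.kmer_engine import (
    DEFAULT_K,
    SampleKmerSet,
    canonical_window_codes,
    canonicalize_kmer,
    encode_kmer,
)
from kseed.seqio import read_fasta

HOM_REF, HET, HOM_ALT, MISSING = "0/0", "0/1", "1/1", "./."


@dataclass
class ReferenceKmerIndex:
    """Exact-position index of every canonical k-mer of a reference."""

    name: str
    k: int
    positions: dict[int, list[tuple[str, int, str]]] = field(repr=False)
    # code -> [(contig, 0-based offset, strand)]; strand '+' means the
    # forward slice at that offset is already canonical, '-' that its
    # reverse complement is.

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        code = encode_kmer(canonicalize_kmer(kmer))
        return self.positions.get(code, [])

    def __contains__(self, kmer: str) -> bool:
        return bool(self.lookup(kmer))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class AnchorHit:
    kmer: str
    hits: list[tuple[str, str, int, str]]  # (reference, contig, offset, strand)

    @property
    def anchored(self) -> bool:
        return bool(self.hits)


def build_reference_index(
    fasta: str | Path | Mapping[str, str], k: int = DEFAULT_K, name: str | None = None
) -> ReferenceKmerIndex:
    """Index all canonical k-mers of a FASTA (path or {contig: seq})."""
    if isinstance(fasta, (str, Path)):
        seqs = read_fasta(fasta)
        name = name or Path(fasta).stem
    else:
        seqs = dict(fasta)
        name = name or "reference"
    positions: dict[int, list[tuple[str, int, str]]] = {}
    for contig, seq in seqs.items():
        if len(seq) < k:
            continue
        codes = canonical_window_codes([seq], k)
        # strand bookkeeping needs the forward codes too
        n_win = len(seq) - k + 1
        offsets = [i for i in range(n_win) if "N" not in seq[i : i + k]] if "N" in seq else range(n_win)
        for off, code in zip(offsets, codes):
            fwd = seq[off : off + k]
            strand = "+" if encode_kmer(fwd) == int(code) else "-"
            positions.setdefault(int(code), []).append((contig, off, strand))
    return ReferenceKmerIndex(name=name, k=k, positions=positions)


def anchor_kmer(kmer: str, indexes: Sequence[ReferenceKmerIndex]) -> AnchorHit:
    """Aggregate exact hits for one k-mer across reference indexes."""
    hits: list[tuple[str, str, int, str]] = []
    for index in indexes:
        if len(kmer) != index.k:
            raise ValueError(f"k-mer length {len(kmer)} != index k {index.k}")
        hits.extend((index.name, contig, off, strand) for contig, off, strand in index.lookup(kmer))
    return AnchorHit(kmer=kmer, hits=hits)


@dataclass
class KmerPartition:
    """Bonferroni-significant k-mers split by anchoring outcome."""

    anchored: list[AnchorHit]
    unanchored: list[str]  # candidate structural-variant k-mers, ascending p


def classify_significant_kmers(result, indexes: Sequence[ReferenceKmerIndex]) -> KmerPartition:
    """Partition a GwasResult's significant k-mers into anchored/unanchored.

    Unanchored significant k-mers are the structural-variant candidates;
    they inherit the result's ascending-p order.
    """
    if not result.records:
        raise ValueError("empty GWAS result")
    anchored, unanchored = [], []
    for record in result.records:
        if not record.significant:
            continue
        hit = anchor_kmer(record.kmer, indexes)
        if hit.anchored:
            anchored.append(hit)
        else:
            unanchored.append(record.kmer)
    return KmerPartition(anchored=anchored, unanchored=unanchored)


@dataclass
class SiteKmerPair:
    """Ref- and alt-tagging canonical k-mers for one biallelic SNP site."""

    contig: str
    pos: int  # 0-based on the reference sequence
    ref: str
    alt: str
    ref_kmers: frozenset[str]
    alt_kmers: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.ref_kmers) != len(self.alt_kmers):
            raise ValueError("ref and alt k-mer sets must pair up")
        if self.ref_kmers & self.alt_kmers:
            raise ValueError("ref and alt k-mer sets must be disjoint")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)


def build_site_kmer_pairs(
    ref_seq: str,
    snp_sites: Sequence[tuple[int, str, str]],
    k: int = DEFAULT_K,
    contig: str = "ancestral",
) -> list[SiteKmerPair]:
    """Derive allele-tagging k-mers for each SNP from the reference sequence.

    A site whose k-window would overlap another listed variant is skipped
    (its ref/alt k-mer pair is ambiguous), as is the rare site where the
    canonical ref and alt sets collide.
    """
    pairs: list[SiteKmerPair] = []
    sorted_pos = sorted(p for p, _, _ in snp_sites)
    for pos, ref, alt in snp_sites:
        if ref_seq[pos] != ref:
            raise ValueError(f"reference base at {pos} is {ref_seq[pos]}, expected {ref}")
        neighbors = [q for q in sorted_pos if q != pos and abs(q - pos) < k]
        if neighbors:
            continue
        lo = max(0, pos - k + 1)
        hi = min(len(ref_seq) - k, pos)
        ref_kmers, alt_kmers = set(), set()
        alt_seq = ref_seq[:pos] + alt + ref_seq[pos + 1 :]
        for start in range(lo, hi + 1):
            ref_kmers.add(canonicalize_kmer(ref_seq[start : start + k]))
            alt_kmers.add(canonicalize_kmer(alt_seq[start : start + k]))
        if ref_kmers & alt_kmers:
            continue
        pairs.append(
            SiteKmerPair(
                contig=contig,
                pos=pos,
                ref=ref,
                alt=alt,
                ref_kmers=frozenset(ref_kmers),
                alt_kmers=frozenset(alt_kmers),
            )
        )
    return pairs


def infer_site_genotypes_from_kmers(
    pairs: Sequence[SiteKmerPair], sample_set: SampleKmerSet
) -> dict[tuple[str, int], str]:
    """Call genotypes from k-mer presence: ref-only 0/0, alt-only 1/1,
    both 0/1, neither ./. ."""
    calls: dict[tuple[str, int], str] = {}
    for pair in pairs:
        has_ref = any(kmer in sample_set for kmer in pair.ref_kmers)
        has_alt = any(kmer in sample_set for kmer in pair.alt_kmers)
        if has_ref and has_alt:
            call = HET
        elif has_ref:
            call = HOM_REF
        elif has_alt:
            call = HOM_ALT
        else:
            call = MISSING
        calls[pair.key] = call
    return calls


@dataclass
class ConcordanceReport:
    """Genotype-level agreement between k-mer calls and reference calls.

    Concordance is genotype-level: a comparison unit is one (site, sample)
    pair where both call sets are non-missing; a match requires the exact
    same diploid genotype (0/0, 0/1, 1/1).
    """

    n_sites: int
    n_genotypes: int
    n_matching: int
    per_locus: dict[str, float] = field(default_factory=dict)

    @property
    def percent(self) -> float:
        return 100.0 * self.n_matching / self.n_genotypes


def read_vcf_genotypes(path: str | Path) -> pd.DataFrame:
    """Load diploid GT strings from a VCF: rows (contig, pos0), columns samples."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    index, rows = [], []
    code_map = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}
    for variant in vcf:
        index.append((variant.CHROM, variant.POS - 1))
        rows.append([code_map.get(int(t), MISSING) for t in variant.gt_types])
    vcf.close()
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["contig", "pos"]), columns=samples)


def genotype_concordance(
    kmer_calls: Mapping[str, Mapping[tuple[str, int], str]] | pd.DataFrame,
    reference_calls: pd.DataFrame | str | Path,
    regions: Mapping[str, tuple[str, int, int]] | None = None,
) -> ConcordanceReport:
    """Score k-mer-derived genotypes against reference-based calls.

    ``kmer_calls`` maps sample -> {(contig, pos0): GT} (or an equivalent
    DataFrame shaped like :func:`read_vcf_genotypes` output);
    ``reference_calls`` is such a DataFrame or a VCF path.  Genotypes
    missing on either side are excluded from the denominator; zero
    comparable genotypes is an error, never reported as 0%.
    ``regions`` maps locus name -> (contig, start, end), 0-based half-open,
    for a per-locus breakdown.
    """
    if isinstance(reference_calls, (str, Path)):
        reference_calls = read_vcf_genotypes(reference_calls)
    if isinstance(kmer_calls, pd.DataFrame):
        kmer_map = {
            sample: dict(zip(kmer_calls.index, kmer_calls[sample])) for sample in kmer_calls.columns
        }
    else:
        kmer_map = {s: dict(m) for s, m in kmer_calls.items()}

    sites = [key for key in reference_calls.index if any(key in m for m in kmer_map.values())]
    shared_samples = [s for s in reference_calls.columns if s in kmer_map]
    n_genotypes = n_matching = 0
    per_locus_counts: dict[str, list[int]] = {name: [0, 0] for name in (regions or {})}
    compared_sites = set()
    for key in sites:
        contig, pos = key
        for sample in shared_samples:
            km = kmer_map[sample].get(key, MISSING)
            rf = reference_calls.at[key, sample]
            if km == MISSING or rf == MISSING:
                continue
            compared_sites.add(key)
            n_genotypes += 1
            match = int(km == rf)
            n_matching += match
            for name, (rcontig, start, end) in (regions or {}).items():
                if contig == rcontig and start <= pos < end:
                    per_locus_counts[name][0] += 1
                    per_locus_counts[name][1] += match
    if n_genotypes == 0:
        raise ValueError("no comparable genotypes between the two call sets")
    per_locus = {
        name: 100.0 * m / n for name, (n, m) in per_locus_counts.items() if n > 0
    }
    return ConcordanceReport(
        n_sites=len(compared_sites),
        n_genotypes=n_genotypes,
        n_matching=n_matching,
        per_locus=per_locus,
    )
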