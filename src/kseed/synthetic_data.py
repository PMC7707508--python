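"""Synthetic cohorts segregating a recombinant chalcone-synthase locus.

The generator builds a pair of haplotypes that reproduce, structurally, the
situation the pipeline is designed to detect:

* an *ancestral* haplotype carrying an intact subtilisin gene, a spacer,
  and a CHS cluster in which CHS3 sits as an inverted, nearly identical
  (>99%) copy of CHS1, followed by a pre-existing intergenic segment (the
  future novel exon) and CHS4;
* a *recombinant* haplotype in which the 3' portion of subtilisin and the
  spacer are deleted, fusing the subtilisin 5' exons directly onto the CHS
  cluster with a single non-templated base at the breakpoint.  The fusion
  creates a chimeric gene whose new intron contains the CHS1/CHS3 inverted
  pair (a hairpin precursor once spliced out) and whose new terminal exon
  is the previously intergenic segment between CHS3 and CHS4.

Because the recombinant haplotype is otherwise a sub-arrangement of the
ancestral one, the canonical 31-mer set difference recombinant-minus-
ancestral is exactly the 31 k-mers containing the breakpoint base — the
synthetic analogue of a junction k-mer absent from every reference.

Cohorts attach a "colorless hilum" phenotype to the recombinant allele with
configurable penetrance and leak, plant biallelic SNPs in shared flanks
under Hardy–Weinberg genotypes, and read simulators emit WGR, spliced-mRNA
and adapter-carrying small-RNA reads with i.i.d. substitution errors.
All randomness fans out from per-stage integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from kseed.kmer_engine import DEFAULT_K, canonicalize_kmer, kmer_set_of_sequence
from kseed.rna_evidence import GeneModel
from kseed.seqio import FastqRecord, revcomp, write_fasta

ANCESTRAL, RECOMBINANT = "ancestral", "recombinant"
CHIMERIC_GENE = "SC1C3"
SUBTILISIN, CHS1, CHS3, CHS4, CHS7 = "subtilisin", "CHS1", "CHS3", "CHS4", "CHS7"
COLORLESS = "colorless"

# Widely used small-RNA library 3' adapter; any reference-absent sequence works.
DEFAULT_SRNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """i.i.d. substitutions at `rate`; no indels."""
    vals = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    hit = rng.random(len(vals)) < rate
    vals[hit] = (vals[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return _BASES[vals].tobytes().decode()


def _identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("alignment-free identity needs equal lengths")
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class LocusBlueprint:
    """Structural parameters of the synthetic locus pair.

    Defaults give an ancestral haplotype of roughly 50 kb with a >99%
    CHS1/CHS3 arm identity, the regime in which the inverted pair can fold
    into a stable hairpin after splicing.
    """

    flank_len: int = 20_000
    subtilisin_exons: tuple[int, ...] = (260, 230, 250, 300, 420)
    subtilisin_intron_len: int = 180
    spacer_len: int = 1_600
    chs_gene_len: int = 1_800
    chs_intron: tuple[int, int] = (600, 400)  # (start offset, length) within a CHS gene
    chs13_identity: float = 0.995
    linker_len: int = 350
    novel_exon_len: int = 260
    chs7_len: int = 1_615
    chs7_match_len: int = 120
    n_snps: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = (
            self.flank_len, self.subtilisin_intron_len, self.spacer_len,
            self.chs_gene_len, self.linker_len, self.novel_exon_len,
            self.chs7_len, *self.subtilisin_exons,
        )
        if any(x <= 0 for x in lengths):
            raise ValueError("all lengths must be positive")
        if len(self.subtilisin_exons) < 4:
            raise ValueError("subtilisin needs at least 4 exons")
        off, ilen = self.chs_intron
        if not (0 < off and 0 < ilen and off + ilen < self.chs_gene_len):
            raise ValueError("chs_intron must fit strictly inside chs_gene_len")
        if not 0.95 < self.chs13_identity <= 1.0:
            raise ValueError("chs13_identity must be in (0.95, 1.0]")
        if not 0 < self.chs7_match_len <= min(self.chs7_len, off):
            raise ValueError("chs7_match_len must fit in CHS7 and the CHS1 first exon")


@dataclass
class LocusTruth:
    """Ground truth for one ancestral/recombinant haplotype pair."""

    ancestral_seq: str = field(repr=False)
    recombinant_seq: str = field(repr=False)
    junction_pos: int  # 0-based offset of the breakpoint base on recombinant_seq
    deletion: tuple[int, int]  # ancestral interval removed by the recombination
    gene_models: dict[str, list[GeneModel]]
    snp_sites: list[tuple[int, str, str]]  # (ancestral pos, ref, alt)
    chimeric_junctions: list[tuple[int, int]]

    def gene(self, gene_id: str, contig: str = RECOMBINANT) -> GeneModel:
        for model in self.gene_models[contig]:
            if model.gene_id == gene_id:
                return model
        raise KeyError(f"{gene_id} not on {contig}")

    def junction_kmers(self, k: int = DEFAULT_K) -> set[str]:
        """Canonical k-mers of the recombinant overlapping the breakpoint base."""
        p = self.junction_pos
        seq = self.recombinant_seq
        return {
            canonicalize_kmer(seq[s : s + k])
            for s in range(max(0, p - k + 1), min(p, len(seq) - k) + 1)
        }

    def to_recombinant_pos(self, ancestral_pos: int) -> int:
        """Map an ancestral coordinate into recombinant coordinates."""
        del_start, del_end = self.deletion
        if ancestral_pos < del_start:
            return ancestral_pos
        if ancestral_pos < del_end:
            raise ValueError(f"position {ancestral_pos} lies in the deleted segment")
        return ancestral_pos - (del_end - del_start) + 1

    def reference_seqs(self) -> dict[str, str]:
        return {ANCESTRAL: self.ancestral_seq, RECOMBINANT: self.recombinant_seq}


def _chs_exons(offset: int, blueprint: LocusBlueprint) -> list[tuple[int, int]]:
    ioff, ilen = blueprint.chs_intron
    glen = blueprint.chs_gene_len
    return [(offset, offset + ioff), (offset + ioff + ilen, offset + glen)]


def _chs_exons_inverted(offset: int, blueprint: LocusBlueprint) -> list[tuple[int, int]]:
    # gene laid down as the reverse complement: coordinates flip within [0, glen)
    ioff, ilen = blueprint.chs_intron
    glen = blueprint.chs_gene_len
    return [(offset, offset + glen - ioff - ilen), (offset + glen - ioff, offset + glen)]


def build_locus_pair(blueprint: LocusBlueprint) -> LocusTruth:
    """Construct the ancestral/recombinant haplotype pair with full truth.

    Deterministic for a fixed blueprint seed.  The builder verifies that the
    canonical 31-mer difference recombinant-minus-ancestral is exactly the
    31 breakpoint k-mers (retrying the breakpoint base and, if needed, the
    sequence draw on the astronomically rare collision) and that the
    realized CHS1/CHS3 arm identity stays above 0.95.
    """
    for attempt in range(8):
        rng = np.random.default_rng((blueprint.seed, attempt))
        truth = _build_once(blueprint, rng)
        if truth is not None:
            return truth
    raise RuntimeError("could not realize a collision-free breakpoint; widen the locus")


def _build_once(blueprint: LocusBlueprint, rng: np.random.Generator) -> LocusTruth | None:
    bp = blueprint
    flank5 = _random_seq(rng, bp.flank_len)
    exon_seqs = [_random_seq(rng, n) for n in bp.subtilisin_exons]
    intron_seqs = [_random_seq(rng, bp.subtilisin_intron_len) for _ in bp.subtilisin_exons[:-1]]
    spacer = _random_seq(rng, bp.spacer_len)

    chs1 = _random_seq(rng, bp.chs_gene_len)
    mutation_rate = 1.0 - bp.chs13_identity
    chs3_core = _mutate(rng, chs1, mutation_rate) if mutation_rate > 0 else chs1
    if _identity(chs1, chs3_core) < 0.95:
        raise ValueError("realized CHS1/CHS3 identity below 0.95; hairpin assumption broken")
    chs3_seg = revcomp(chs3_core)
    linker1 = _random_seq(rng, bp.linker_len)
    linker2 = _random_seq(rng, bp.linker_len)
    novel = _random_seq(rng, bp.novel_exon_len)
    linker3 = _random_seq(rng, bp.linker_len)
    chs4 = _random_seq(rng, bp.chs_gene_len)

    # CHS7: an unlinked-paralog analogue in the 3' flank — independent
    # sequence apart from one exact block copied from the CHS1 first exon.
    chs7 = _random_seq(rng, bp.chs7_len)
    donor_block = chs1[: bp.chs7_match_len]
    chs7_insert_at = bp.chs7_len // 4
    chs7 = chs7[:chs7_insert_at] + donor_block + chs7[chs7_insert_at + bp.chs7_match_len :]
    # keep the shared block exactly chs7_match_len long: the base after it
    # must not extend the run against CHS1
    boundary = chs7_insert_at + bp.chs7_match_len
    if boundary < len(chs7) and bp.chs7_match_len < len(chs1):
        if chs7[boundary] == chs1[bp.chs7_match_len]:
            swap = "A" if chs1[bp.chs7_match_len] != "A" else "C"
            chs7 = chs7[:boundary] + swap + chs7[boundary + 1 :]
    from kseed.rna_evidence import paralog_perfect_match_coverage

    if paralog_perfect_match_coverage(chs1, chs7, 20).covered_bp != bp.chs7_match_len:
        return None  # chance extra exact block; retry the draw
    flank3 = _random_seq(rng, bp.flank_len)
    chs7_offset_in_flank3 = 500
    flank3 = (
        flank3[:chs7_offset_in_flank3]
        + chs7
        + flank3[chs7_offset_in_flank3 + bp.chs7_len :]
    )

    # assemble the ancestral haplotype
    pieces, coords, pos = [], {}, 0

    def put(name: str, seq: str) -> None:
        nonlocal pos
        coords[name] = (pos, pos + len(seq))
        pieces.append(seq)
        pos += len(seq)

    put("flank5", flank5)
    for i, eseq in enumerate(exon_seqs):
        put(f"sub_e{i + 1}", eseq)
        if i < len(intron_seqs):
            put(f"sub_i{i + 1}", intron_seqs[i])
    put("spacer", spacer)
    put("chs1", chs1)
    put("linker1", linker1)
    put("chs3", chs3_seg)
    put("linker2", linker2)
    put("novel", novel)
    put("linker3", linker3)
    put("chs4", chs4)
    put("flank3", flank3)
    ancestral = "".join(pieces)

    del_start = coords["sub_e4"][1]  # retain subtilisin exons 1-4
    del_end = coords["chs1"][0]  # fuse directly onto the CHS cluster
    del_len = del_end - del_start

    anc_kmers = kmer_set_of_sequence(ancestral, DEFAULT_K)
    recombinant = junction_set = None
    for base in "ACGT":
        candidate = ancestral[:del_start] + base + ancestral[del_end:]
        p = del_start
        windows = {
            canonicalize_kmer(candidate[s : s + DEFAULT_K])
            for s in range(p - DEFAULT_K + 1, p + 1)
        }
        if len(windows) == DEFAULT_K and not (windows & anc_kmers):
            recombinant, junction_set = candidate, windows
            break
    if recombinant is None:
        return None
    # exact set-difference guarantee (desk-scale brute force, part of the contract)
    if kmer_set_of_sequence(recombinant, DEFAULT_K) - anc_kmers != junction_set:
        return None

    def rec(p: int) -> int:
        return p if p < del_start else p - del_len + 1

    sub_exons = [coords[f"sub_e{i + 1}"] for i in range(len(exon_seqs))]
    anc_models = [
        GeneModel(SUBTILISIN, ANCESTRAL, "+", sub_exons),
        GeneModel(CHS1, ANCESTRAL, "+", _chs_exons(coords["chs1"][0], bp)),
        GeneModel(CHS3, ANCESTRAL, "-", _chs_exons_inverted(coords["chs3"][0], bp)),
        GeneModel(CHS4, ANCESTRAL, "+", _chs_exons(coords["chs4"][0], bp)),
    ]
    novel_rec = (rec(coords["novel"][0]), rec(coords["novel"][1]))
    chimeric_exons = sub_exons[:4] + [novel_rec]
    chs7_start = coords["flank3"][0] + chs7_offset_in_flank3
    chs7_mid = chs7_start + bp.chs7_len // 2
    chs7_exons_anc = [(chs7_start, chs7_mid - 100), (chs7_mid, chs7_start + bp.chs7_len)]
    rec_models = [
        GeneModel(CHIMERIC_GENE, RECOMBINANT, "+", chimeric_exons),
        GeneModel(CHS1, RECOMBINANT, "+", _chs_exons(rec(coords["chs1"][0]), bp)),
        GeneModel(CHS3, RECOMBINANT, "-", _chs_exons_inverted(rec(coords["chs3"][0]), bp)),
        GeneModel(CHS4, RECOMBINANT, "+", _chs_exons(rec(coords["chs4"][0]), bp)),
        GeneModel(CHS7, RECOMBINANT, "+", [(rec(s), rec(e)) for s, e in chs7_exons_anc]),
    ]
    anc_models.append(GeneModel(CHS7, ANCESTRAL, "+", chs7_exons_anc))

    chimeric_gene = rec_models[0]
    snp_sites = _plant_snps(rng, ancestral, coords, bp, del_start, del_end)
    return LocusTruth(
        ancestral_seq=ancestral,
        recombinant_seq=recombinant,
        junction_pos=del_start,
        deletion=(del_start, del_end),
        gene_models={ANCESTRAL: anc_models, RECOMBINANT: rec_models},
        snp_sites=snp_sites,
        chimeric_junctions=chimeric_gene.junctions(),
    )


def _plant_snps(
    rng: np.random.Generator,
    ancestral: str,
    coords: dict[str, tuple[int, int]],
    bp: LocusBlueprint,
    del_start: int,
    del_end: int,
) -> list[tuple[int, str, str]]:
    """Pick well-separated SNP positions in the shared flanks."""
    k = DEFAULT_K
    margin = 3 * k
    windows = [
        (coords["flank5"][0] + margin, coords["flank5"][1] - margin),
        (coords["flank3"][0] + margin, coords["flank3"][1] - margin),
    ]
    candidates = np.concatenate([np.arange(lo, hi) for lo, hi in windows])
    rng.shuffle(candidates)
    chosen: list[int] = []
    for p in candidates:
        if len(chosen) == bp.n_snps:
            break
        if del_start - k < p < del_end + k:
            continue
        if all(abs(p - q) >= margin for q in chosen):
            chosen.append(int(p))
    sites = []
    for p in sorted(chosen):
        ref = ancestral[p]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        sites.append((p, ref, str(alt)))
    return sites


@dataclass
class CohortSpec:
    """Cohort size and the phenotype-allele linkage parameters.

    `penetrance` is the probability a recombinant-allele carrier shows the
    colorless-hilum category; `leak` the probability a non-carrier does.
    Defaults emulate the contrast reported for the junction k-mer's
    subpopulations (~95.5% vs ~1.3% presence).

    `inbreeding` is the probability that a sample is autozygous at a SNP
    site; the default of 1.0 models germplasm accessions of a selfing crop
    as fully homozygous inbred lines.  Lower it to inject Hardy-Weinberg
    heterozygotes.
    """

    n_accessions: int = 60
    recomb_allele_freq: float = 0.3
    penetrance: float = 0.955
    leak: float = 0.013
    inbreeding: float = 1.0
    seed_coat_categories: tuple[str, ...] = ("black", "brown", "yellow", "green")
    hilum_categories: tuple[str, ...] = ("black", "brown", COLORLESS)
    pubescence_categories: tuple[str, ...] = ("tawny", "gray", "brown")
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.recomb_allele_freq, self.penetrance, self.leak, self.inbreeding):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_accessions < 2:
            raise ValueError("need at least 2 accessions")
        for cats in (self.seed_coat_categories, self.hilum_categories, self.pubescence_categories):
            if len(cats) < 2:
                raise ValueError("each trait needs at least 2 categories")
        if COLORLESS not in self.hilum_categories:
            raise ValueError(f"hilum categories must include {COLORLESS!r}")


@dataclass
class Cohort:
    """Per-sample alleles, trait labels and planted SNP genotypes."""

    sample_ids: list[str]
    alleles: np.ndarray  # 0 ancestral, 1 recombinant
    traits: pd.DataFrame  # index sample_id; columns seed_coat, hilum, pubescence
    snp_genotypes: pd.DataFrame  # index sample_id; one column per SNP pos; 0/1/2 alt copies
    spec: CohortSpec

    @property
    def carriers(self) -> list[str]:
        return [s for s, a in zip(self.sample_ids, self.alleles) if a == 1]


def simulate_cohort(
    spec: CohortSpec,
    truth: LocusTruth,
    snp_maf_range: tuple[float, float] = (0.1, 0.5),
) -> Cohort:
    """Draw alleles, linked hilum phenotypes, and HWE SNP genotypes."""
    rng = np.random.default_rng((spec.seed, 1))
    n = spec.n_accessions
    sample_ids = [f"acc{i + 1:04d}" for i in range(n)]
    alleles = (rng.random(n) < spec.recomb_allele_freq).astype(np.int8)

    colored = [c for c in spec.hilum_categories if c != COLORLESS]
    p_colorless = np.where(alleles == 1, spec.penetrance, spec.leak)
    is_colorless = rng.random(n) < p_colorless
    hilum = np.where(is_colorless, COLORLESS, rng.choice(colored, size=n))
    traits = pd.DataFrame(
        {
            "seed_coat": rng.choice(spec.seed_coat_categories, size=n),
            "hilum": hilum,
            "pubescence": rng.choice(spec.pubescence_categories, size=n),
        },
        index=pd.Index(sample_ids, name="accession_id"),
    )

    lo, hi = snp_maf_range
    mafs = rng.uniform(lo, hi, size=len(truth.snp_sites))
    autozygous = rng.random((n, len(mafs))) < spec.inbreeding
    hwe = rng.binomial(2, mafs, size=(n, len(mafs)))
    homozygous = 2 * rng.binomial(1, mafs, size=(n, len(mafs)))
    genotypes = np.where(autozygous, homozygous, hwe).astype(np.int8)
    snp_genotypes = pd.DataFrame(
        genotypes,
        index=traits.index,
        columns=[pos for pos, _, _ in truth.snp_sites],
    )
    return Cohort(
        sample_ids=sample_ids,
        alleles=alleles,
        traits=traits,
        snp_genotypes=snp_genotypes,
        spec=spec,
    )


def sample_haplotypes(truth: LocusTruth, cohort: Cohort, sample_id: str) -> tuple[str, str]:
    """The two haplotype sequences of one sample.

    The locus allele is shared by both haplotypes (the cohort segregates it
    as a homozygous background); heterozygous SNPs place the alt base on the
    second haplotype.
    """
    i = cohort.sample_ids.index(sample_id)
    base = truth.recombinant_seq if cohort.alleles[i] else truth.ancestral_seq
    on_recombinant = bool(cohort.alleles[i])
    haps = [list(base), list(base)]
    for pos, _, alt in truth.snp_sites:
        gt = int(cohort.snp_genotypes.iloc[i][pos])
        if gt == 0:
            continue
        p = truth.to_recombinant_pos(pos) if on_recombinant else pos
        if gt >= 1:
            haps[1][p] = alt
        if gt == 2:
            haps[0][p] = alt
    return "".join(haps[0]), "".join(haps[1])


@dataclass
class ReadSimParams:
    """Shotgun read simulation parameters.

    Default depth 15x reflects a typical resequencing panel average; errors
    are i.i.d. substitutions and qualities are a constant placeholder
    (the pipeline never consumes them).
    """

    read_len: int = 100
    depth: float = 15.0
    err: float = 0.01
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.err < 0.25:
            raise ValueError("err must be in [0, 0.25)")
        if self.read_len < 31:
            raise ValueError("read_len must be at least 31")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def _emit_reads(
    seq: str,
    n_reads: int,
    read_len: int,
    err: float,
    rng: np.random.Generator,
    id_prefix: str,
) -> list[FastqRecord]:
    """Uniform-start single-end reads with substitution errors, random strand."""
    vals = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    starts = rng.integers(0, len(seq) - read_len + 1, size=n_reads)
    mat = vals[starts[:, None] + np.arange(read_len)]
    if err > 0:
        hit = rng.random(mat.shape) < err
        mat[hit] = (mat[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    flip = rng.random(n_reads) < 0.5
    mat[flip] = (3 - mat[flip])[:, ::-1]
    chars = _BASES[mat]
    qual = "I" * read_len
    return [
        FastqRecord(f"{id_prefix}:{i}", chars[i].tobytes().decode(), qual)
        for i in range(n_reads)
    ]


def simulate_wgr_reads(
    sample_seq: str, params: ReadSimParams, id_prefix: str = "read"
) -> list[FastqRecord]:
    """Whole-genome resequencing reads of one haplotype sequence.

    Read count is round(depth * len / read_len); in paired mode the same
    budget is emitted as pairs flanking fixed-length fragments.
    """
    if params.read_len > len(sample_seq):
        raise ValueError("read_len exceeds sequence length")
    rng = np.random.default_rng((params.seed, 2))
    if not params.paired:
        n_reads = round(params.depth * len(sample_seq) / params.read_len)
        return _emit_reads(sample_seq, n_reads, params.read_len, params.err, rng, id_prefix)

    rl = params.read_len
    frag_len = min(2 * rl + 50, len(sample_seq))
    n_pairs = round(params.depth * len(sample_seq) / (2 * rl))
    starts = rng.integers(0, len(sample_seq) - frag_len + 1, size=n_pairs)
    out: list[FastqRecord] = []
    for i, s in enumerate(starts):
        frag = sample_seq[s : s + frag_len]
        r1 = _mutate(rng, frag[:rl], params.err) if params.err else frag[:rl]
        r2_src = revcomp(frag[-rl:])
        r2 = _mutate(rng, r2_src, params.err) if params.err else r2_src
        out.append(FastqRecord(f"{id_prefix}:{i}/1", r1, "I" * rl))
        out.append(FastqRecord(f"{id_prefix}:{i}/2", r2, "I" * rl))
    return out


def simulate_cohort_reads(
    truth: LocusTruth, cohort: Cohort, params: ReadSimParams
) -> Iterator[tuple[str, list[FastqRecord]]]:
    """Per-sample WGR reads, half the depth from each haplotype."""
    for i, sample_id in enumerate(cohort.sample_ids):
        hap1, hap2 = sample_haplotypes(truth, cohort, sample_id)
        hap_params = ReadSimParams(
            read_len=params.read_len,
            depth=params.depth / 2,
            err=params.err,
            paired=params.paired,
            seed=params.seed + 101 + 2 * i,
        )
        reads = simulate_wgr_reads(hap1, hap_params, id_prefix=f"{sample_id}.h1")
        hap_params2 = ReadSimParams(
            read_len=params.read_len,
            depth=params.depth / 2,
            err=params.err,
            paired=params.paired,
            seed=params.seed + 102 + 2 * i,
        )
        reads += simulate_wgr_reads(hap2, hap_params2, id_prefix=f"{sample_id}.h2")
        yield sample_id, reads


def simulate_mrna_reads(
    truth: LocusTruth, params: ReadSimParams, gene_id: str = CHIMERIC_GENE
) -> list[FastqRecord]:
    """Reads from the spliced chimeric transcript (intron, and thus the
    CHS1/CHS3 hairpin cassette, removed)."""
    gene = truth.gene(gene_id, RECOMBINANT)
    if not gene.junctions():
        raise ValueError("gene model has no splice junctions")
    transcript = gene.transcript_sequence(truth.recombinant_seq)
    rng = np.random.default_rng((params.seed, 3))
    n_reads = round(params.depth * len(transcript) / params.read_len)
    return _emit_reads(transcript, n_reads, params.read_len, params.err, rng, "mrna")


def simulate_small_rna_reads(
    truth: LocusTruth,
    n_primary: int,
    n_secondary: int,
    adapter: str = DEFAULT_SRNA_ADAPTER,
    seed: int = 0,
    raw_len: int = 52,
    offsize_frac: float = 0.15,
) -> list[FastqRecord]:
    """Adapter-carrying small-RNA reads.

    Primary reads are 21-24 nt substrings of the CHS1/CHS3 hairpin arms
    (inside the chimeric gene's intron); secondary reads are 21-24 nt
    substrings of CHS paralog exons, never their introns.  A minority
    fraction (`offsize_frac`) of inserts is drawn uniformly from 14-43 nt
    to emulate degradation tails, keeping the trimmed-length mode at
    21-24 nt.  The 3' adapter is appended and reads are cut to `raw_len`.
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    rng = np.random.default_rng((seed, 4))
    seq = truth.recombinant_seq
    arm_spans = [truth.gene(CHS1).span, truth.gene(CHS3).span]
    exon_pool: list[tuple[int, int]] = []
    for gene_id in (CHS1, CHS3, CHS4, CHS7):
        exon_pool.extend(truth.gene(gene_id).exons)

    def draw_len() -> int:
        if rng.random() < offsize_frac:
            return int(rng.integers(14, 44))
        return int(rng.integers(21, 25))

    def make_read(source: tuple[int, int], prefix: str, i: int) -> FastqRecord:
        lo, hi = source
        length = draw_len()
        length = min(length, hi - lo)
        start = int(rng.integers(lo, hi - length + 1))
        insert = seq[start : start + length]
        if rng.random() < 0.5:
            insert = revcomp(insert)
        raw = (insert + adapter)[:raw_len]
        return FastqRecord(f"{prefix}:{i}", raw, "I" * len(raw))

    reads = [
        make_read(arm_spans[int(rng.integers(0, 2))], "srna_p", i) for i in range(n_primary)
    ]
    exon_lens = np.array([e - s for s, e in exon_pool], dtype=float)
    exon_probs = exon_lens / exon_lens.sum()
    for i in range(n_secondary):
        exon = exon_pool[int(rng.choice(len(exon_pool), p=exon_probs))]
        reads.append(make_read(exon, "srna_s", i))
    return reads


def simulate_null_presence(
    n_samples: int,
    n_kmers: int,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.15, 0.85),
    k: int = DEFAULT_K,
):
    """A presence matrix with no genotype-phenotype structure at all.

    Random distinct canonical k-mers, each present in a random subset of
    samples at a per-k-mer frequency drawn from `freq_range` — the null
    model for type-I-error calibration of the association scan.
    """
    from kseed.kmer_engine import encode_kmer
    from kseed.kmer_gwas import PresenceMatrix

    rng = np.random.default_rng((seed, 5))
    kmers: set[str] = set()
    while len(kmers) < n_kmers:
        draw = _BASES[rng.integers(0, 4, size=(n_kmers, k))]
        for row in draw:
            kmers.add(canonicalize_kmer(row.tobytes().decode()))
            if len(kmers) == n_kmers:
                break
    codes = np.sort(np.array([encode_kmer(m) for m in kmers], dtype=np.uint64))
    freqs = rng.uniform(*freq_range, size=n_kmers)
    presence = rng.random((n_kmers, n_samples)) < freqs[:, None]
    sample_ids = [f"acc{i + 1:04d}" for i in range(n_samples)]
    return PresenceMatrix(sample_ids=sample_ids, codes=codes, presence=presence, k=k)


# ---------------------------------------------------------------------------
# writers


def write_reference_fasta(truth: LocusTruth, path: str | Path) -> None:
    write_fasta({ANCESTRAL: truth.ancestral_seq, RECOMBINANT: truth.recombinant_seq}, path)


def write_gff3(truth: LocusTruth, path: str | Path, contigs: Sequence[str] = (ANCESTRAL, RECOMBINANT)) -> None:
    """Gene models as GFF3 (1-based inclusive coordinates on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in contigs:
            seq = truth.reference_seqs()[contig]
            fh.write(f"##sequence-region {contig} 1 {len(seq)}\n")
        for contig in contigs:
            for gene in truth.gene_models[contig]:
                gid = f"{gene.gene_id}.{contig}"
                start, end = gene.span
                fh.write(
                    f"{contig}\tkseed\tgene\t{start + 1}\t{end}\t.\t{gene.strand}\t.\tID={gid}\n"
                )
                for j, (s, e) in enumerate(gene.exons, start=1):
                    fh.write(
                        f"{contig}\tkseed\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                        f"ID={gid}.exon{j};Parent={gid}\n"
                    )


def write_truth_vcf(truth: LocusTruth, cohort: Cohort, path: str | Path) -> None:
    """Planted SNP genotypes as a VCFv4.2 on the ancestral contig."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ANCESTRAL},length={len(truth.ancestral_seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for pos, ref, alt in sorted(truth.snp_sites):
            gts = "\t".join(
                gt_str[int(cohort.snp_genotypes.loc[s, pos])] for s in cohort.sample_ids
            )
            fh.write(f"{ANCESTRAL}\t{pos + 1}\tsnp_{pos}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def write_phenotypes(cohort: Cohort, path: str | Path) -> None:
    cohort.traits.to_csv(path, sep="\t")


def write_truth_alleles(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame(
        {"accession_id": cohort.sample_ids, "allele": np.where(cohort.alleles == 1, RECOMBINANT, ANCESTRAL)}
    ).to_csv(path, sep="\t", index=False)
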