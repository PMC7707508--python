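# Methods

## The model in brief

`kseed` treats each accession's whole-genome resequencing reads as a bag of
canonical 31-mers.  A k-mer is *canonical* when it is the lexicographically
smaller of itself and its reverse complement (A<C<G<T), which makes
counting independent of sequencing strand.  After dropping k-mers observed
only once (the singleton filter: a k-mer seen once in shotgun data is most
plausibly a read error), the per-accession k-mer set is the genotype.
Association is the 1-df Pearson chi-squared on the 2×2 presence table of a
k-mer against a case/control bipartition of a categorical color trait,
with Bonferroni control over the retained k-mers.  A significant k-mer
with no exact occurrence in any supplied reference assembly is a
structural-variant candidate; on the synthetic truth these are exactly the
k-mers that span the recombination breakpoint.

## The synthetic locus

The generator produces two haplotypes of a pigmentation locus:

* **ancestral** — 5' flank, an intact multi-exon subtilisin gene, a
  spacer, then a CHS cluster: CHS1, a linker, CHS3 laid down as the
  reverse complement of a near-identical copy of CHS1 (default identity
  0.995, substitutions only), a short intergenic segment that will become
  the novel exon, and CHS4; a diverged CHS7 analogue sits in the 3' flank,
  sharing exactly one 120 bp block with CHS1's first exon (1,615 bp total,
  so perfect-match coverage is 120/1615 = 7.43%).
* **recombinant** — the interval from the end of subtilisin exon 4 to the
  start of CHS1 (subtilisin 3' portion + spacer) is deleted and replaced
  by a single non-templated base, fusing the subtilisin 5' exons onto the
  CHS cluster.  The resulting chimeric gene splices subtilisin exons 1–4
  to the previously intergenic novel terminal exon; its new intron
  contains the CHS1/CHS3 inverted pair, which after splicing can fold into
  a long hairpin — the mirtron-style silencing trigger.

Because the recombinant haplotype is otherwise a sub-arrangement of
ancestral segments, the canonical 31-mer set difference
recombinant − ancestral is exactly the 31 k-mers containing the breakpoint
base.  The builder verifies this by brute-force set difference (and the
CHS7 block length by perfect-match coverage) and re-draws on the
astronomically rare collision, so the truth object is exact by
construction, not by expectation.  The two haplotypes are structural
analogues of the real locus, not base-level reconstructions; no indels,
CNVs or quality-score error profiles are modeled.

Defaults give an ancestral haplotype of ~50.5 kb — large enough that the
presence matrix contains thousands of haplotype-tagging and SNP-tagging
rows, small enough that a 60-accession cohort at 15× simulates and counts
in seconds.

## Cohort and phenotype model

Alleles are drawn i.i.d. at `recomb_allele_freq` (default 0.3); the locus
allele is homozygous within an accession.  The colorless-hilum category
appears with probability `penetrance` (default 0.955) in carriers and
`leak` (default 0.013) in non-carriers — the contrast chosen to emulate
the reported ~95.5% vs ~1.3% subpopulation presence of the junction
k-mer.  Seed-coat and pubescence labels are independent noise traits, so
binarizations on them are null scans.

SNPs (default 36) are planted in the shared flanks, at least 93 bp apart
and away from the breakpoint, with per-site minor-allele frequencies
uniform on [0.1, 0.5].  The cohort defaults to fully inbred lines
(`inbreeding = 1.0`, genotypes 0/0 or 1/1 only), the realistic regime for
a selfing crop's germplasm panel; lowering `inbreeding` injects
Hardy–Weinberg heterozygotes.  This matters for concordance: at 15× total
(7.5× per haplotype) a heterozygote can lose one allele's k-mers to
coverage dropout and be miscalled, so a panel with hets cannot reach
exact concordance at zero error rate — inbred lines can, and do.

## Read simulation

Shotgun reads have uniform start positions on the linear haplotype,
random strand, i.i.d. substitution errors (`err`, default 0.01) and
constant placeholder qualities (`I`); read count is
round(depth × length / read_len).  Uniform linear starts imply linearly
attenuated coverage within one read length of the sequence ends; tests
and acceptance checks are formulated to be robust to this edge effect
(SNPs and the breakpoint are interior).  Paired mode emits fixed-length
fragments' ends; no insert-size distribution is modeled.

mRNA reads are drawn the same way from the spliced chimeric transcript, so
zero reads originate in the removed intron; at depth 50 each splice
junction collects comfortably more than the 5 spanning reads used as the
evidence bar (a read spans a junction when it matches the spliced
transcript exactly across the boundary with ≥ 8 bases on each side).

Small-RNA reads are 21–24 nt inserts (with a 15% degradation tail uniform
on 14–43 nt) from either the CHS1/CHS3 hairpin arms ("primary") or CHS
paralog exons, never introns ("secondary"), with a 3' library adapter
appended and the read cut at 52 nt.  Adapter detection scans for the most
frequent reference-absent 12-mer carried by ≥ 20% of reads and extends it
greedily; trimming cuts at the adapter's leading 8-mer and keeps reads of
14–43 nt.  Mapping is exact-occurrence on both strands with all hits
reported — multi-mapping between near-identical hairpin arms is the
phenomenon of interest, not a nuisance to resolve.

## Association details

* Presence is coded per sample (dominant 2×2): a k-mer has no diploid
  dosage from presence alone.
* The presence-frequency filter removes rows with frequency < 0.05 or
  > 0.95 (boundary values retained), the k-mer analogue of a MAF cut; it
  also removes monomorphic rows, which carry no signal.
* No kinship or population-structure correction is applied in this arm;
  the pseudo-VCF header carries that caveat.  The synthetic cohort has no
  structure, so the null calibration checks the nominal type-I rate
  directly.
* Degenerate tables (an empty margin) return chi2 = 0, p = 1 rather than
  NaN.  Ties in p are broken by k-mer lexicographic order for determinism.
* The pseudo-VCF encoding (contig `KMERS`, POS = rank, ID = k-mer,
  REF/ALT placeholders A/T, 0/0 vs 1/1 genotypes) is a declared
  convention validated by lossless round-trip through cyvcf2; association
  results are computed from the matrix, never from the VCF text.

## Genotype concordance

Ref- and alt-tagging canonical k-mer sets are derived for each planted SNP
(up to 31 windows each; sites whose window overlaps another variant are
skipped as ambiguous).  Calls: only ref k-mers present → 0/0, only alt →
1/1, both → 0/1, neither → missing.  Concordance is genotype-level —
matching diploid calls over (site, sample) pairs with both sides
non-missing — and a run with zero comparable genotypes is an error, never
0%.  Het calling from joint presence is an extension beyond pure
presence/absence logic and is stated in the report.

## Numerical and design choices

* k-mers are packed 2 bits/base into uint64 codes; numeric order equals
  lexicographic order, so sorted code arrays serve as both index and
  canonical ordering.  Counting is vectorized numpy (k shift-or passes per
  read batch) with windows containing non-ACGT symbols dropped entirely.
* k defaults to 31 and is capped at 31 by the 64-bit packing; the counting
  is in-memory, sized for desk-scale cohorts rather than terabase runs.
* Coordinates are 0-based half-open internally; GFF3 and VCF emission is
  1-based per the format specs.
* One integer seed fans out to per-stage generators by fixed offsets, so
  stages are independently reproducible; identical seeds give
  byte-identical FASTA/FASTQ output.
* Paralog perfect-match coverage marks a subject position covered iff it
  lies in a shared 20-mer window (both orientations), which is provably
  the same set of positions as the union of maximal exact matches ≥ 20 bp;
  a quadratic scan validates this in the tests.
* The acceptance script runs the study at its default size (60 accessions,
  ~50 kb, 15×, 2,500-k-mer null scan), the package's chosen desk-scale
  study conditions.

## What passing tests do and do not show

The synthetic cohort has clean structure: no population stratification or
kinship, no indels or CNVs, uniform coverage, a single biallelic
structural event, and error rates that are i.i.d. substitutions.  Passing
the suite therefore demonstrates the pipeline's correctness and its
statistical behaviour under its own assumptions — calibrated nulls,
perfect junction recovery at the stated depth and error rate, concordance
in the high-90s — not robustness to confounded real panels, repetitive
genomes beyond the built-in inverted repeat, or library artifacts beyond a
single 3' adapter.  On real data the missing ingredients (structure
correction, coverage normalization across heterogeneous libraries) would
need to be addressed upstream or the results read with those caveats.
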