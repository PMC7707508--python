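"""Shared fixtures: a desk-scale locus pair and cohort, built once.

The small blueprint (~7 kb ancestral haplotype) keeps brute-force oracles
(quadratic recounts, exhaustive substring scans) fast; study-scale runs
live in the acceptance tests with their own module-scoped fixtures.
"""

import pytest

from kseed import synthetic_data as sd


@pytest.fixture(scope="session")
def small_blueprint() -> sd.LocusBlueprint:
    return sd.LocusBlueprint(
        flank_len=1500,
        subtilisin_exons=(120, 100, 110, 130, 150),
        subtilisin_intron_len=80,
        spacer_len=400,
        chs_gene_len=600,
        chs_intron=(200, 150),
        chs13_identity=0.995,
        linker_len=120,
        novel_exon_len=120,
        chs7_len=400,
        chs7_match_len=60,
        n_snps=6,
        seed=2,
    )


@pytest.fixture(scope="session")
def small_truth(small_blueprint) -> sd.LocusTruth:
    return sd.build_locus_pair(small_blueprint)


@pytest.fixture(scope="session")
def small_cohort(small_truth) -> sd.Cohort:
    spec = sd.CohortSpec(n_accessions=16, recomb_allele_freq=0.4, seed=5)
    return sd.simulate_cohort(spec, small_truth)
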