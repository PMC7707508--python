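"""Presence matrix, pseudo-VCF round trip, binarization and association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kseed import kmer_engine as ke
from kseed import kmer_gwas as kg


def sets_from_sequences(seqs_by_sample, k=31):
    return [
        ke.SampleKmerSet(sample_id=s, k=k, codes=ke.sequence_kmer_codes(seq, k))
        for s, seq in seqs_by_sample.items()
    ]


class TestPresenceMatrix:
    def test_monomorphic_kmers_removed(self):
        rng = np.random.default_rng(1)
        shared = "".join(rng.choice(list("ACGT"), size=100))
        sets = sets_from_sequences({f"s{i}": shared for i in range(3)})
        matrix = kg.build_presence_matrix(sets, min_freq=0.05)
        assert matrix.n_kmers == 0

    def test_boundary_frequency_retained(self):
        # present in 1 of 20 samples: frequency 0.05 is not < 0.05 -> kept
        kmer = "ACGTACGTACGTACGTACGTACGTACGTACG"
        code = np.array([ke.encode_kmer(ke.canonicalize_kmer(kmer))], dtype=np.uint64)
        empty = np.empty(0, dtype=np.uint64)
        sets = [
            ke.SampleKmerSet(f"s{i}", 31, code if i == 0 else empty) for i in range(20)
        ]
        # add one shared k-mer so the union is nonempty for all samples
        matrix = kg.build_presence_matrix(sets, min_freq=0.05)
        assert matrix.n_kmers == 1
        assert matrix.frequency[0] == pytest.approx(0.05)

    def test_mismatched_k_rejected(self):
        a = ke.SampleKmerSet("a", 31, np.empty(0, dtype=np.uint64))
        b = ke.SampleKmerSet("b", 21, np.empty(0, dtype=np.uint64))
        with pytest.raises(ValueError, match="mismatched k"):
            kg.build_presence_matrix([a, b])

    def test_junction_kmers_are_retained_rows(self, small_truth):
        # haplotype k-mer sets at an intermediate allele frequency
        seqs = {}
        for i in range(10):
            hap = small_truth.recombinant_seq if i < 4 else small_truth.ancestral_seq
            seqs[f"s{i}"] = hap
        matrix = kg.build_presence_matrix(sets_from_sequences(seqs))
        for kmer in small_truth.junction_kmers():
            assert kmer in matrix

    def test_sample_permutation_changes_only_column_order(self, small_truth):
        seqs = {
            "a": small_truth.ancestral_seq,
            "b": small_truth.recombinant_seq,
            "c": small_truth.ancestral_seq,
        }
        m1 = kg.build_presence_matrix(sets_from_sequences(seqs))
        shuffled = {k: seqs[k] for k in ["c", "a", "b"]}
        m2 = kg.build_presence_matrix(sets_from_sequences(shuffled))
        perm = [m2.sample_ids.index(s) for s in m1.sample_ids]
        assert np.array_equal(m1.codes, m2.codes)
        assert np.array_equal(m1.presence, m2.presence[:, perm])


class TestPseudoVcf:
    def test_single_kmer_body_line(self, tmp_path):
        kmer = "A" * 30 + "C"
        code = np.array([ke.encode_kmer(kmer)], dtype=np.uint64)
        matrix = kg.PresenceMatrix(
            sample_ids=["present", "absent"],
            codes=code,
            presence=np.array([[True, False]]),
            k=31,
        )
        path = tmp_path / "one.vcf"
        kg.write_pseudo_vcf(matrix, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 1
        fields = body[0].split("\t")
        assert fields[:5] == ["KMERS", "1", kmer, "A", "T"]
        assert fields[9:] == ["1/1", "0/0"]

    def test_roundtrip_through_standards_compliant_parser(self, tmp_path, small_truth):
        seqs = {
            "s1": small_truth.ancestral_seq,
            "s2": small_truth.recombinant_seq,
            "s3": small_truth.ancestral_seq[: len(small_truth.ancestral_seq) // 2],
        }
        matrix = kg.build_presence_matrix(sets_from_sequences(seqs))
        path = tmp_path / "pseudo.vcf"
        kg.write_pseudo_vcf(matrix, path)
        back = kg.read_pseudo_vcf(path)
        assert back.sample_ids == matrix.sample_ids
        assert np.array_equal(back.codes, matrix.codes)
        assert np.array_equal(back.presence, matrix.presence)
        # record count conservation
        n_body = sum(
            1 for l in path.read_text().splitlines() if not l.startswith("#")
        )
        assert n_body == matrix.n_kmers


class TestBinarization:
    @staticmethod
    def traits_for(labels):
        return pd.DataFrame(
            {"hilum": labels}, index=[f"s{i}" for i in range(len(labels))]
        )

    def test_two_categories_one_bipartition(self):
        traits = self.traits_for(["black", "colorless", "black"])
        assert len(kg.enumerate_binarizations(["black", "colorless"], traits, "hilum")) == 1

    def test_three_categories_exhaustive(self):
        traits = self.traits_for(["A", "B", "C", "A"])
        bins = kg.enumerate_binarizations(["A", "B", "C"], traits, "hilum")
        partitions = {frozenset((b.case_categories, b.control_categories)) for b in bins}
        expected = {
            frozenset((frozenset({"A"}), frozenset({"B", "C"}))),
            frozenset((frozenset({"B"}), frozenset({"A", "C"}))),
            frozenset((frozenset({"C"}), frozenset({"A", "B"}))),
        }
        assert partitions == expected

    @pytest.mark.parametrize("c,expected", [(2, 1), (3, 3), (4, 7), (5, 15)])
    def test_bipartition_count(self, c, expected):
        cats = [f"cat{i}" for i in range(c)]
        traits = self.traits_for(cats * 2)
        assert len(kg.enumerate_binarizations(cats, traits, "hilum")) == expected

    def test_empty_sample_side_dropped(self):
        traits = self.traits_for(["A", "A", "B"])  # category C has no samples
        bins = kg.enumerate_binarizations(["A", "B", "C"], traits, "hilum")
        # {C}|{A,B} leaves the case side without samples and is dropped
        partitions = {frozenset((b.case_categories, b.control_categories)) for b in bins}
        assert frozenset((frozenset({"C"}), frozenset({"A", "B"}))) not in partitions
        assert len(bins) == 2
        for b in bins:
            assert b.case_samples and b.control_samples

    def test_missing_labels_excluded(self):
        traits = self.traits_for(["A", None, "B", "NA"])
        bins = kg.enumerate_binarizations(["A", "B"], traits, "hilum")
        (b,) = bins
        assert set(b.case_samples) | set(b.control_samples) == {"s0", "s2"}


class TestAllelicAssociation:
    def test_equal_proportions_null(self):
        chi2, p, _ = kg.allelic_association(10, 30, 5, 15)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_balanced_separation_closed_form(self):
        # diagonal table with equal margins: chi2 equals n
        chi2, p, _ = kg.allelic_association(10, 0, 0, 10)
        assert chi2 == pytest.approx(20.0)
        assert p < 1e-4

    def test_printed_junction_kmer_table_below_plotted_threshold(self):
        chi2, p, odds = kg.allelic_association(2, 152, 64, 3)
        oracle = stats.chi2_contingency([[2, 152], [64, 3]], correction=False)
        assert chi2 == pytest.approx(oracle.statistic, rel=1e-12)
        assert p == pytest.approx(oracle.pvalue, rel=1e-10)
        assert p < 5e-9
        assert odds < 1  # k-mer depleted in this case group

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            kg.allelic_association(-1, 5, 5, 5)

    def test_degenerate_margin_gives_null(self):
        chi2, p, _ = kg.allelic_association(0, 10, 0, 12)
        assert (chi2, p) == (0.0, 1.0)

    @given(
        st.tuples(
            st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
        ).filter(lambda t: t[0] + t[1] >= 1 and t[2] + t[3] >= 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_label_swap_symmetry(self, table):
        a, b, c, d = table
        chi2, p, odds = kg.allelic_association(a, b, c, d)
        chi2_sw, p_sw, odds_sw = kg.allelic_association(c, d, a, b)
        assert chi2 == pytest.approx(chi2_sw, abs=1e-12)
        assert p == pytest.approx(p_sw, abs=1e-12)
        assert odds * odds_sw == pytest.approx(1.0, rel=1e-9)


class TestRunGwas:
    @staticmethod
    def separating_matrix(n_noise=49, n_samples=60, seed=23):
        rng = np.random.default_rng(seed)
        status = np.arange(n_samples) < n_samples // 2
        rows = [status.copy()]
        while len(rows) < n_noise + 1:
            row = rng.random(n_samples) < rng.uniform(0.2, 0.8)
            if 0.05 <= row.mean() <= 0.95:
                rows.append(row)
        kmers = set()
        while len(kmers) < len(rows):
            kmers.add("".join(rng.choice(list("ACGT"), size=31)))
        codes = np.sort(
            np.array(
                [ke.encode_kmer(ke.canonicalize_kmer(m)) for m in kmers], dtype=np.uint64
            )
        )
        ids = [f"s{i}" for i in range(n_samples)]
        matrix = kg.PresenceMatrix(ids, codes, np.array(rows), 31)
        return matrix, status, ids

    def test_perfectly_separating_kmer_ranks_first(self):
        matrix, status, ids = self.separating_matrix()
        b = kg.Binarization(
            trait="hilum",
            case_categories=frozenset({"colorless"}),
            control_categories=frozenset({"other"}),
            case_samples=tuple(s for s, c in zip(ids, status) if c),
            control_samples=tuple(s for s, c in zip(ids, status) if not c),
        )
        result = kg.run_kmer_gwas(matrix, b)
        top = result.records[0]
        assert top.a == len(b.case_samples) and top.c == 0
        assert top.significant
        assert result.threshold == pytest.approx(0.05 / matrix.n_kmers)

    def test_fixed_threshold_override(self):
        matrix, status, ids = self.separating_matrix(n_noise=9)
        b = kg.Binarization(
            trait="t",
            case_categories=frozenset({"x"}),
            control_categories=frozenset({"y"}),
            case_samples=tuple(s for s, c in zip(ids, status) if c),
            control_samples=tuple(s for s, c in zip(ids, status) if not c),
        )
        result = kg.run_kmer_gwas(matrix, b, fixed_threshold=5e-9)
        assert result.threshold == 5e-9
        for r in result.records:
            assert r.significant == (r.p <= 5e-9)

    def test_records_sorted_by_p_then_kmer(self):
        matrix, status, ids = self.separating_matrix(n_noise=20)
        b = kg.Binarization(
            trait="t",
            case_categories=frozenset({"x"}),
            control_categories=frozenset({"y"}),
            case_samples=tuple(s for s, c in zip(ids, status) if c),
            control_samples=tuple(s for s, c in zip(ids, status) if not c),
        )
        records = kg.run_kmer_gwas(matrix, b).records
        keys = [(r.p, r.kmer) for r in records]
        assert keys == sorted(keys)

    def test_empty_side_rejected(self):
        matrix, status, ids = self.separating_matrix(n_noise=5)
        b = kg.Binarization(
            trait="t",
            case_categories=frozenset({"x"}),
            control_categories=frozenset({"y"}),
            case_samples=("not_in_matrix",),
            control_samples=tuple(ids),
        )
        with pytest.raises(ValueError, match="empty"):
            kg.run_kmer_gwas(matrix, b)


class TestLocusSpan:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (53_087_195, 53_269_307, 182),
            (17_683_675, 19_248_187, 1_565),
            (8_360_663, 8_622_831, 262),
            (45_576_015, 45_939_643, 364),
            (1_000, 2_000, 1),
        ],
    )
    def test_reported_locus_spans(self, start, end, expected):
        assert kg.locus_span_kbp(start, end) == expected

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            kg.locus_span_kbp(10, 10)
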