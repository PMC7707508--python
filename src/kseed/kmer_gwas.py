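"""Presence/absence k-mer GWAS: matrix, pseudo-VCF, binarization, association.

The association model is deliberately simple: each canonical k-mer is a
dominant biallelic marker (present / absent in a sample's filtered k-mer
set), the phenotype is a case/control bipartition of categorical color
labels, and the test is the 1-df Pearson chi-squared on the 2x2 table of
presence by status — the behaviour of PLINK's basic ``--assoc`` on
pseudo-genotypes.  Family-wise error is controlled by Bonferroni over the
number of retained k-mers, with an optional fixed threshold override.

No kinship or structure correction is applied in this arm; output headers
carry that caveat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from kseed.kmer_engine import SampleKmerSet, decode_kmer, encode_kmer

logger = logging.getLogger(__name__)

MISSING_LABELS = {"", "NA", "N/A", "missing", None}


@dataclass
class PresenceMatrix:
    """Binary k-mer x sample presence matrix after the frequency filter."""

    sample_ids: list[str]
    codes: np.ndarray = field(repr=False)  # sorted uint64, lexicographic k-mer order
    presence: np.ndarray = field(repr=False)  # bool, shape (n_kmers, n_samples)
    k: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.codes), len(self.sample_ids)):
            raise ValueError("presence shape must be (n_kmers, n_samples)")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(np.unique(self.codes)) != len(self.codes):
            raise ValueError("duplicate k-mer keys")

    @property
    def n_kmers(self) -> int:
        return len(self.codes)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def frequency(self) -> np.ndarray:
        """Presence frequency per k-mer across samples."""
        return self.presence.mean(axis=1)

    def kmers(self) -> Iterator[str]:
        for code in self.codes:
            yield decode_kmer(int(code), self.k)

    def row_of(self, kmer: str) -> int:
        code = np.uint64(encode_kmer(kmer))
        i = int(np.searchsorted(self.codes, code))
        if i < len(self.codes) and self.codes[i] == code:
            return i
        raise KeyError(kmer)

    def __contains__(self, kmer: str) -> bool:
        try:
            self.row_of(kmer)
            return True
        except (KeyError, ValueError):
            return False


def build_presence_matrix(
    sets: Sequence[SampleKmerSet], min_freq: float = 0.05
) -> PresenceMatrix:
    """Union per-sample k-mer sets and apply the presence-frequency filter.

    Rows with presence frequency strictly below ``min_freq`` or strictly
    above ``1 - min_freq`` are removed — the k-mer analogue of a minor
    allele frequency cut, which also discards monomorphic (all-present)
    k-mers that carry no association signal.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 samples")
    ks = {s.k for s in sets}
    if len(ks) != 1:
        raise ValueError(f"mismatched k across samples: {sorted(ks)}")
    (k,) = ks
    if not 0 <= min_freq < 0.5:
        raise ValueError("min_freq must be in [0, 0.5)")
    union = np.unique(np.concatenate([s.codes for s in sets]))
    presence = np.zeros((len(union), len(sets)), dtype=bool)
    for j, s in enumerate(sets):
        presence[np.searchsorted(union, s.codes), j] = True
    freq = presence.mean(axis=1)
    keep = (freq >= min_freq) & (freq <= 1.0 - min_freq)
    return PresenceMatrix(
        sample_ids=[s.sample_id for s in sets],
        codes=union[keep],
        presence=presence[keep],
        k=k,
    )


def write_pseudo_vcf(matrix: PresenceMatrix, path: str | Path) -> None:
    """Emit the presence matrix as a biallelic pseudo-VCF.

    Encoding convention: one record per k-mer on synthetic contig ``KMERS``,
    POS = 1-based rank in lexicographic k-mer order, ID = the k-mer itself,
    REF=A / ALT=T placeholders, genotype 1/1 when the k-mer is present in a
    sample and 0/0 when absent.  The file is standards-compliant VCFv4.2 and
    round-trips losslessly.
    """
    if matrix.n_kmers == 0:
        raise ValueError("refusing to write an empty pseudo-VCF")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=KMERS,length={matrix.n_kmers}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "##kseed_pseudo_vcf=presence/absence encoding; 1/1=present, 0/0=absent; "
            "no kinship/structure correction applied downstream\n"
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for pos, (kmer, row) in enumerate(zip(matrix.kmers(), matrix.presence), start=1):
            gts = "\t".join("1/1" if p else "0/0" for p in row)
            fh.write(f"KMERS\t{pos}\t{kmer}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def read_pseudo_vcf(path: str | Path) -> PresenceMatrix:
    """Rebuild a PresenceMatrix from a pseudo-VCF (inverse of write)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    codes, rows, k = [], [], None
    for variant in vcf:
        kmer = variant.ID
        k = len(kmer)
        codes.append(encode_kmer(kmer))
        rows.append(variant.gt_types == 3)  # cyvcf2: 3 == HOM_ALT
    vcf.close()
    if k is None:
        raise ValueError("pseudo-VCF contains no records")
    codes_arr = np.asarray(codes, dtype=np.uint64)
    order = np.argsort(codes_arr)
    presence = np.asarray(rows, dtype=bool)[order]
    return PresenceMatrix(sample_ids=sample_ids, codes=codes_arr[order], presence=presence, k=k)


@dataclass(frozen=True)
class Binarization:
    """One case/control bipartition of a categorical trait."""

    trait: str
    case_categories: frozenset[str]
    control_categories: frozenset[str]
    case_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.case_categories & self.control_categories:
            raise ValueError("case and control categories overlap")
        if set(self.case_samples) & set(self.control_samples):
            raise ValueError("case and control samples overlap")
        if not self.case_samples or not self.control_samples:
            raise ValueError("case and control sides must both be nonempty")


def enumerate_binarizations(
    categories: Sequence[str],
    traits: pd.DataFrame,
    trait: str,
) -> list[Binarization]:
    """All case/control bipartitions of a trait's category set.

    For ``c`` categories there are ``2**(c-1) - 1`` unordered bipartitions
    into two nonempty parts; a bipartition that leaves one side without any
    samples is dropped with a warning.  ``traits`` is indexed by sample id
    with one column per trait; missing labels are excluded.
    """
    cats = list(dict.fromkeys(categories))
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    labels = traits[trait]
    labels = labels[~labels.isin(MISSING_LABELS) & labels.notna()]
    by_cat = {c: tuple(labels.index[labels == c]) for c in cats}
    out: list[Binarization] = []
    rest = cats[1:]
    for mask in range(1, 2 ** len(rest)):
        case = frozenset(c for i, c in enumerate(rest) if mask >> i & 1)
        control = frozenset(cats) - case
        case_samples = tuple(s for c in sorted(case) for s in by_cat[c])
        control_samples = tuple(s for c in sorted(control) for s in by_cat[c])
        if not case_samples or not control_samples:
            logger.warning(
                "dropping bipartition %s | %s of trait %s: one side has no samples",
                sorted(case), sorted(control), trait,
            )
            continue
        out.append(
            Binarization(
                trait=trait,
                case_categories=case,
                control_categories=control,
                case_samples=case_samples,
                control_samples=control_samples,
            )
        )
    return out


def binarize_trait(
    traits: pd.DataFrame, trait: str, case_categories: Iterable[str]
) -> Binarization:
    """Build a single Binarization with the given categories as cases."""
    case = frozenset(case_categories)
    labels = traits[trait]
    labels = labels[~labels.isin(MISSING_LABELS) & labels.notna()]
    control = frozenset(labels.unique()) - case
    return Binarization(
        trait=trait,
        case_categories=case,
        control_categories=control,
        case_samples=tuple(labels.index[labels.isin(case)]),
        control_samples=tuple(labels.index[labels.isin(control)]),
    )


def _chi2_vectorized(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson 1-df chi-squared on 2x2 tables, no continuity correction.

    Degenerate margins (an all-zero row or column) yield chi2=0, p=1.
    """
    a, b, c, d = (x.astype(np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    ok = denom > 0
    chi2 = np.zeros_like(n)
    np.divide(n * (a * d - b * c) ** 2, denom, out=chi2, where=ok)
    p = np.where(ok, stats.chi2.sf(chi2, df=1), 1.0)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return chi2, p


def _odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """(a*d)/(b*c) with the Haldane–Anscombe +0.5 substitute on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def allelic_association(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Chi-squared, p-value and odds ratio for one presence 2x2 table.

    ``a``/``b``: cases with/without the k-mer; ``c``/``d``: controls
    with/without.  Returns (chi2, p, odds_ratio).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b < 1 or c + d < 1:
        raise ValueError("each of cases and controls must be nonempty")
    chi2, p = _chi2_vectorized(*(np.asarray([x]) for x in (a, b, c, d)))
    return float(chi2[0]), float(p[0]), _odds_ratio(a, b, c, d)


@dataclass
class AssociationRecord:
    kmer: str
    a: int  # cases with k-mer
    b: int  # cases without
    c: int  # controls with
    d: int  # controls without
    chi2: float
    p: float
    odds_ratio: float
    fisher_p: float | None = None
    significant: bool = False


@dataclass
class GwasResult:
    binarization: Binarization
    records: list[AssociationRecord]
    m_tests: int
    alpha: float
    threshold: float

    def significant_records(self) -> list[AssociationRecord]:
        return [r for r in self.records if r.significant]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kmer": [r.kmer for r in self.records],
                "a": [r.a for r in self.records],
                "b": [r.b for r in self.records],
                "c": [r.c for r in self.records],
                "d": [r.d for r in self.records],
                "chi2": [r.chi2 for r in self.records],
                "p": [r.p for r in self.records],
                "fisher_p": [r.fisher_p for r in self.records],
                "OR": [r.odds_ratio for r in self.records],
                "significant": [r.significant for r in self.records],
            }
        )

    def manhattan_table(self) -> pd.DataFrame:
        """Rank vs -log10 p, for Manhattan-style plotting."""
        p = np.array([r.p for r in self.records])
        return pd.DataFrame(
            {"rank": np.arange(1, len(p) + 1), "neg_log10_p": -np.log10(p)}
        )


def run_kmer_gwas(
    matrix: PresenceMatrix,
    binarization: Binarization,
    alpha: float = 0.05,
    fixed_threshold: float | None = None,
) -> GwasResult:
    """Test every retained k-mer against one case/control bipartition.

    Bonferroni threshold = alpha / n_retained_kmers unless a fixed override
    is supplied.  Records are sorted by ascending p with lexicographic
    k-mer tie-break.  Fisher's exact p is reported additionally whenever any
    expected cell is < 5; ranking is always by the chi-squared p.
    """
    sample_pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    case_idx = [sample_pos[s] for s in binarization.case_samples if s in sample_pos]
    control_idx = [sample_pos[s] for s in binarization.control_samples if s in sample_pos]
    if not case_idx or not control_idx:
        raise ValueError("case or control side empty after intersecting with matrix samples")

    n_cases, n_controls = len(case_idx), len(control_idx)
    a = matrix.presence[:, case_idx].sum(axis=1)
    c = matrix.presence[:, control_idx].sum(axis=1)
    b = n_cases - a
    d = n_controls - c
    chi2, p = _chi2_vectorized(a, b, c, d)

    m = matrix.n_kmers
    threshold = fixed_threshold if fixed_threshold is not None else alpha / m
    significant = p <= threshold

    n = float(n_cases + n_controls)
    expected_min = np.minimum(a + b, c + d) * np.minimum(a + c, b + d) / n
    needs_fisher = expected_min < 5

    order = np.lexsort((matrix.codes, p))
    records = []
    for i in order:
        fisher_p = None
        if needs_fisher[i]:
            fisher_p = float(
                stats.fisher_exact([[a[i], b[i]], [c[i], d[i]]], alternative="two-sided")[1]
            )
        records.append(
            AssociationRecord(
                kmer=decode_kmer(int(matrix.codes[i]), matrix.k),
                a=int(a[i]),
                b=int(b[i]),
                c=int(c[i]),
                d=int(d[i]),
                chi2=float(chi2[i]),
                p=float(p[i]),
                odds_ratio=_odds_ratio(int(a[i]), int(b[i]), int(c[i]), int(d[i])),
                fisher_p=fisher_p,
                significant=bool(significant[i]),
            )
        )
    return GwasResult(
        binarization=binarization,
        records=records,
        m_tests=m,
        alpha=alpha,
        threshold=float(threshold),
    )


def locus_span_kbp(start: int, end: int) -> int:
    """Span of a 1-based genomic range in kbp, rounded half away from zero."""
    if end <= start:
        raise ValueError("end must be greater than start")
    return int(math.floor((end - start) / 1000.0 + 0.5))
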