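"""Fixed-difference scanning: oracle equivalence, recovery of planted
loci, ordering, missingness policy, and per-sample summaries."""

import itertools

import numpy as np
import pytest

import indelmark as im
from indelmark.core import MISSING, GroupedGenotypeMatrix, IndelLocus
from indelmark.errors import ConfigurationError
from indelmark.scan import (
    STATUS_DIAGNOSTIC,
    STATUS_INDETERMINATE,
    STATUS_NON_DIAGNOSTIC,
    MissingPolicy,
    classify_locus,
    load_matrix,
    summarize_samples,
)

GENOTYPES = [(0, 0), (0, 1), (1, 1), (MISSING, MISSING)]
LOCUS = IndelLocus(chrom="chr1", pos=100, ref="ATTTT", alts=("A",))


def _matrix(gt_a, gt_b):
    """Single-locus matrix from per-group genotype lists."""
    samples = [f"A{i}" for i in range(len(gt_a))] + [f"B{i}" for i in range(len(gt_b))]
    group_of = {s: s[0] for s in samples}
    gt = np.array([list(gt_a) + list(gt_b)], dtype=np.int16)
    return GroupedGenotypeMatrix(
        loci=[LOCUS], samples=samples, group_of=group_of, gt=gt, groups=("A", "B")
    )


def oracle_predicate(gt_a, gt_b, max_missing):
    """Literal restatement of the diagnostic condition: each group uniformly
    homozygous over its called samples, for two different alleles, with
    missingness within policy — checked by direct enumeration."""
    miss_a = [g for g in gt_a if MISSING in g]
    miss_b = [g for g in gt_b if MISSING in g]
    called_a = [g for g in gt_a if MISSING not in g]
    called_b = [g for g in gt_b if MISSING not in g]
    if len(miss_a) > max_missing or len(miss_b) > max_missing:
        return STATUS_INDETERMINATE
    if not called_a or not called_b:
        return STATUS_INDETERMINATE
    alleles_a = {a for g in called_a for a in g}
    alleles_b = {a for g in called_b for a in g}
    hom_a = all(g[0] == g[1] for g in called_a) and len(alleles_a) == 1
    hom_b = all(g[0] == g[1] for g in called_b) and len(alleles_b) == 1
    if hom_a and hom_b and alleles_a != alleles_b:
        return STATUS_DIAGNOSTIC
    return STATUS_NON_DIAGNOSTIC


@pytest.mark.parametrize("max_missing", [0, 1])
def test_classifier_matches_oracle_on_all_two_plus_two_configurations(max_missing):
    policy = MissingPolicy(max_missing_per_group=max_missing)
    for cfg in itertools.product(GENOTYPES, repeat=4):
        gt_a, gt_b = cfg[:2], cfg[2:]
        call = classify_locus(_matrix(gt_a, gt_b), 0, policy)
        assert call.status == oracle_predicate(gt_a, gt_b, max_missing), cfg


def test_seven_vs_seven_fixed_difference_is_diagnostic():
    call = classify_locus(_matrix([(0, 0)] * 7, [(1, 1)] * 7), 0)
    assert call.status == STATUS_DIAGNOSTIC
    assert (call.group_a_allele, call.group_b_allele) == (0, 1)
    assert call.contrast_length_bp == 4


def test_monomorphic_site_is_non_diagnostic():
    call = classify_locus(_matrix([(0, 0)] * 7, [(0, 0)] * 7), 0)
    assert call.status == STATUS_NON_DIAGNOSTIC


def test_half_call_counts_as_missing():
    # one group-A half-call under zero tolerance -> indeterminate
    call = classify_locus(_matrix([(0, MISSING), (0, 0)], [(1, 1), (1, 1)]), 0)
    assert call.status == STATUS_INDETERMINATE
    assert call.n_missing_a == 1


def test_scan_recovers_exactly_the_planted_set(small_dataset):
    calls = im.scan.scan(small_dataset["matrix"])
    found = {(c.locus.chrom, c.locus.pos) for c in calls}
    assert found == small_dataset["truth"].positions("diagnostic")


def test_scan_orders_longest_first_with_positional_tiebreak():
    loci = [
        IndelLocus("chr1", 500, "A" + "T" * 10, ("A",)),
        IndelLocus("chr1", 100, "A" + "T" * 5, ("A",)),
        IndelLocus("chr2", 50, "A" + "T" * 5, ("A",)),
    ]
    samples = ["A1", "B1"]
    gt = np.array([[[1, 1], [0, 0]]] * 3, dtype=np.int16)
    m = GroupedGenotypeMatrix(loci=loci, samples=samples,
                              group_of={"A1": "A", "B1": "B"}, gt=gt)
    out = im.scan.scan(m)
    assert [(c.locus.chrom, c.locus.pos) for c in out] == [
        ("chr1", 500), ("chr1", 100), ("chr2", 50)
    ]


def test_missingness_policy_is_monotone(study_scale_dataset, rng):
    """The diagnostic set under max_missing=k is a subset of k+1."""
    matrix = study_scale_dataset["matrix"]
    gt = matrix.gt.copy()
    mask = rng.random(gt.shape[:2]) < 0.05
    gt[mask] = MISSING
    noisy = GroupedGenotypeMatrix(
        loci=matrix.loci, samples=matrix.samples,
        group_of=matrix.group_of, gt=gt, groups=matrix.groups,
    )
    previous: set = set()
    for k in range(0, 4):
        found = {
            (c.locus.chrom, c.locus.pos)
            for c in im.scan.scan(noisy, MissingPolicy(max_missing_per_group=k))
        }
        assert previous <= found
        previous = found


def test_single_masked_genotype_tolerated_under_policy(small_dataset):
    matrix = small_dataset["matrix"]
    truth = small_dataset["truth"]
    target = truth.of_class("diagnostic")[0]
    row = next(
        i for i, l in enumerate(matrix.loci)
        if (l.chrom, l.pos) == (target.chrom, target.pos)
    )
    gt = matrix.gt.copy()
    gt[row, matrix.group_columns("A")[0]] = MISSING
    masked = GroupedGenotypeMatrix(
        loci=matrix.loci, samples=matrix.samples,
        group_of=matrix.group_of, gt=gt, groups=matrix.groups,
    )
    strict = {(c.locus.chrom, c.locus.pos) for c in im.scan.scan(masked)}
    tolerant = {
        (c.locus.chrom, c.locus.pos)
        for c in im.scan.scan(masked, MissingPolicy(max_missing_per_group=1))
    }
    assert (target.chrom, target.pos) not in strict
    assert (target.chrom, target.pos) in tolerant


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def _write_vcf(tmp_path, body):
    vcf = tmp_path / "in.vcf"
    vcf.write_text(VCF_HEADER + body)
    groups = tmp_path / "groups.tsv"
    groups.write_text("sample_id\tgroup\nS1\tA\nS2\tB\n")
    return vcf, groups


def test_load_matrix_keeps_indels_and_skips_snps(tmp_path):
    body = (
        "chr1\t100\t.\tA\tATT\t.\t.\t.\tGT\t0/0\t1/1\n"
        "chr1\t200\t.\tC\tG\t.\t.\t.\tGT\t0/0\t1/1\n"  # SNP
        "chr1\t300\t.\tGTT\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
        "chr1\t400\t.\tT\tA\t.\t.\t.\tGT\t0/0\t0/0\n"  # SNP
        "chr1\t500\t.\tT\tTACGT\t.\t.\t.\tGT\t0/0\t./.\n"
    )
    vcf, groups = _write_vcf(tmp_path, body)
    m = load_matrix(vcf, groups)
    assert [l.pos for l in m.loci] == [100, 300, 500]
    assert (m.gt[2, 1] == MISSING).all()


def test_load_matrix_decomposes_multiallelic_indel_alts(tmp_path):
    body = "chr1\t100\t.\tAT\tA,ATTT,AC\t.\t.\t.\tGT\t1/1\t2/2\n"
    vcf, groups = _write_vcf(tmp_path, body)
    m = load_matrix(vcf, groups)
    # AC is a length-preserving alt (not an InDel): 2 decomposed loci
    assert [(l.alt_index, l.alt) for l in m.loci] == [(1, "A"), (2, "ATTT")]
    # genotype indices are the record's own
    assert m.gt[0].tolist() == [[1, 1], [2, 2]]
    # the alt-vs-alt fixed contrast is reported once, with its own length
    calls = im.scan.scan(m)
    assert len(calls) == 1
    assert calls[0].contrast_length_bp == 3  # |len('A') - len('ATTT')|


def test_load_matrix_empty_body_gives_empty_matrix(tmp_path):
    vcf, groups = _write_vcf(tmp_path, "")
    m = load_matrix(vcf, groups)
    assert m.n_loci == 0 and m.samples == ["S1", "S2"]


def test_sample_missing_from_group_table_raises(tmp_path):
    vcf = tmp_path / "in.vcf"
    vcf.write_text(VCF_HEADER)
    groups = tmp_path / "groups.tsv"
    groups.write_text("sample_id\tgroup\nS1\tA\nS9\tB\n")
    with pytest.raises(ConfigurationError, match="S2"):
        load_matrix(vcf, groups)


class TestSampleSummaries:
    def test_counts_each_genotype_class_once(self):
        loci = [IndelLocus("chr1", p, "ATT", ("A",)) for p in (10, 20, 30, 40)]
        gt = np.array(
            [[[0, 0], [1, 1]], [[1, 1], [1, 1]], [[0, 1], [0, 0]],
             [[MISSING, MISSING], [0, 0]]],
            dtype=np.int16,
        )
        m = GroupedGenotypeMatrix(loci=loci, samples=["S1", "S2"],
                                  group_of={"S1": "A", "S2": "B"}, gt=gt)
        row = summarize_samples(m).set_index("sample").loc["S1"]
        assert (
            row.n_ref_homo, row.n_alt_homo, row.n_het, row.n_missing, row.n_total
        ) == (1, 1, 1, 1, 4)

    def test_class_counts_always_sum_to_total(self, study_scale_dataset):
        df = summarize_samples(study_scale_dataset["matrix"])
        assert (
            df.n_ref_homo + df.n_alt_homo + df.n_het + df.n_missing == df.n_total
        ).all()
        assert (df.n_missing == 0).all()  # missing_rate was 0

    def test_group_a_carries_the_alt_alleles(self, study_scale_dataset):
        """The reference belongs to group B, so group-A samples are
        alt-homozygous at every diagnostic site at least."""
        df = summarize_samples(study_scale_dataset["matrix"])
        n_diag = len(study_scale_dataset["truth"].of_class("diagnostic"))
        assert (df.loc[df.group == "A", "n_alt_homo"] >= n_diag).all()


def test_filtered_vcf_contains_exactly_the_diagnostic_calls(small_dataset, tmp_path):
    import pysam

    from indelmark.scan import write_calls_vcf

    matrix = small_dataset["matrix"]
    calls = im.scan.scan(matrix)
    out = tmp_path / "diag.vcf"
    write_calls_vcf(matrix, calls, out)
    with pysam.VariantFile(str(out)) as vcf:
        recs = [(r.chrom, r.pos) for r in vcf]
    assert recs == [(c.locus.chrom, c.locus.pos) for c in calls]
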