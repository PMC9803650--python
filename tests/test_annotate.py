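"""Genomic-context annotation: hand-built cases, a category-painting
oracle, strand symmetry, and summary arithmetic."""

import numpy as np
import pytest

import indelmark as im
from indelmark.annotate import (
    _RANK,
    AnnotationWindows,
    Annotator,
    load_gene_models,
    summarize_categories,
)
from indelmark.core import GeneModel, IndelLocus
from indelmark.errors import DataError


def _locus(chrom, pos):
    return IndelLocus(chrom=chrom, pos=pos, ref="AT", alts=("A",))


@pytest.fixture()
def forward_gene():
    # exons 1000-1199, 1500-1699, 2000-2199 on +; CDS trimmed into terminal exons
    return GeneModel(
        gene_id="g1", transcript_id="t1", chrom="chr1", strand="+",
        start=1000, end=2199,
        exons=((1000, 1199), (1500, 1699), (2000, 2199)),
        cds=((1050, 1199), (1500, 1699), (2000, 2149)),
    )


@pytest.fixture()
def reverse_gene():
    return GeneModel(
        gene_id="g2", transcript_id="t2", chrom="chr1", strand="-",
        start=1000, end=2199,
        exons=((1000, 1199), (1500, 1699), (2000, 2199)),
        cds=((1050, 1199), (1500, 1699), (2000, 2149)),
    )


@pytest.mark.parametrize(
    "pos, strand, expected",
    [
        # intron 1200..1499: on '+' donor is the left end, acceptor the right
        (1200, "+", "splice_site_donor"),
        (1201, "+", "splice_site_donor"),
        (1202, "+", "splice_site_region"),  # 3 bp into the intron
        (1498, "+", "splice_site_acceptor"),  # 2 bp from the 3' intron boundary
        (1499, "+", "splice_site_acceptor"),
        (1493, "+", "splice_site_region"),  # 7 bp from the acceptor end
        (1350, "+", "intron"),
        (1200, "-", "splice_site_acceptor"),  # strand flips donor/acceptor
        (1499, "-", "splice_site_donor"),
        # exonic 3 bp flanking a junction
        (1199, "+", "splice_site_region"),
        (1197, "+", "splice_site_region"),
        (1196, "+", "exon"),
        # UTRs: exonic, outside the CDS span, 5'/3' by strand
        (1020, "+", "utr5"),
        (1020, "-", "utr3"),
        (2180, "+", "utr3"),
        (2180, "-", "utr5"),
        (1100, "+", "exon"),
        # flanks within 5 kb, strand-aware
        (900, "+", "upstream"),
        (900, "-", "downstream"),
        (2500, "+", "downstream"),
        (2500, "-", "upstream"),
        (8000, "+", "intergenic"),  # beyond both windows
    ],
)
def test_positional_categories(forward_gene, reverse_gene, pos, strand, expected):
    gm = forward_gene if strand == "+" else reverse_gene
    ann = Annotator([gm])
    assert ann.annotate_position("chr1", pos) == expected


def test_transcript_without_exon_structure():
    gm = GeneModel(gene_id="g", transcript_id="t", chrom="chr1",
                   strand="+", start=100, end=500)
    assert Annotator([gm]).annotate_position("chr1", 300) == "transcript"


def test_unknown_chromosome_lenient_none_strict_error(forward_gene):
    assert Annotator([forward_gene]).annotate_position("chrZ", 5) == "none"
    with pytest.raises(DataError):
        Annotator([forward_gene], strict=True).annotate_position("chrZ", 5)


def test_overlapping_transcripts_resolve_to_most_specific(forward_gene):
    # a second, intron-less transcript spanning the same region: its plain
    # 'exon' must not shadow the first transcript's splice-site calls
    blanket = GeneModel(gene_id="g3", transcript_id="t3", chrom="chr1",
                        strand="+", start=900, end=2500, exons=((900, 2500),))
    ann = Annotator([forward_gene, blanket])
    assert ann.annotate_position("chr1", 1200) == "splice_site_donor"
    # at 1350 the blanket transcript's 'exon' outranks the intron call
    assert ann.annotate_position("chr1", 1350) == "exon"


def paint_oracle(models, chrom_len, w: AnnotationWindows):
    """Independent oracle: paint per-base category ranks over the whole
    chromosome, one transcript at a time, keeping the minimum rank."""
    grid = np.full(chrom_len + 1, _RANK["intergenic"], dtype=int)

    def paint(lo, hi, cat):
        lo, hi = max(1, lo), min(chrom_len, hi)
        if lo <= hi:
            grid[lo : hi + 1] = np.minimum(grid[lo : hi + 1], _RANK[cat])

    for gm in models:
        fwd = gm.strand == "+"
        paint(gm.start - (w.upstream if fwd else w.downstream), gm.start - 1,
              "upstream" if fwd else "downstream")
        paint(gm.end + 1, gm.end + (w.downstream if fwd else w.upstream),
              "downstream" if fwd else "upstream")
        if not gm.exons:
            paint(gm.start, gm.end, "transcript")
            continue
        for s, e in gm.exons:
            paint(s, e, "exon")
        if gm.cds:
            cds_lo, cds_hi = gm.cds[0][0], gm.cds[-1][1]
            for s, e in gm.exons:
                for p in range(s, e + 1):
                    if p < cds_lo:
                        paint(p, p, "utr5" if fwd else "utr3")
                    elif p > cds_hi:
                        paint(p, p, "utr3" if fwd else "utr5")
        for i, (s, e) in enumerate(gm.exons):
            if i > 0:
                paint(s, s + w.splice_region_exon - 1, "splice_site_region")
            if i < len(gm.exons) - 1:
                paint(e - w.splice_region_exon + 1, e, "splice_site_region")
        for s, e in gm.introns:
            paint(s, e, "intron")
            donor = (s, s + w.splice_site - 1) if fwd else (e - w.splice_site + 1, e)
            acceptor = (e - w.splice_site + 1, e) if fwd else (s, s + w.splice_site - 1)
            lo_r, hi_r = w.splice_region_intron
            if fwd:
                paint(s + lo_r - 1, s + hi_r - 1, "splice_site_region")
                paint(e - hi_r + 1, e - lo_r + 1, "splice_site_region")
            else:
                paint(e - hi_r + 1, e - lo_r + 1, "splice_site_region")
                paint(s + lo_r - 1, s + hi_r - 1, "splice_site_region")
            paint(*donor, "splice_site_donor")
            paint(*acceptor, "splice_site_acceptor")
    return grid


def test_annotator_agrees_with_painting_oracle_on_random_positions(small_dataset, rng):
    models = small_dataset["reference"].gene_models
    chrom_len = len(small_dataset["reference"].sequences["chr1"])
    w = AnnotationWindows()
    grid = paint_oracle(models, chrom_len, w)
    ann = Annotator(models, w)
    inv_rank = {v: k for k, v in _RANK.items()}
    for pos in rng.integers(1, chrom_len + 1, size=1000):
        got = ann.annotate_position("chr1", int(pos))
        assert got == inv_rank[grid[pos]], f"pos {pos}"


def test_strand_symmetry(small_dataset):
    """Two complementary symmetries, checked per transcript: (1)
    reverse-complementing the genome (mirror coordinates + flip strand)
    leaves every category unchanged, because the biology is unchanged;
    (2) flipping a transcript's strand in place swaps donor<->acceptor,
    upstream<->downstream and utr5<->utr3, fixing the neutral classes.
    (Across overlapping transcripts the asymmetric precedence tie-breaks
    make the combined call direction-dependent by design.)"""
    models = small_dataset["reference"].gene_models
    L = len(small_dataset["reference"].sequences["chr1"])
    swap = {
        "splice_site_donor": "splice_site_acceptor",
        "splice_site_acceptor": "splice_site_donor",
        "upstream": "downstream",
        "downstream": "upstream",
        "utr5": "utr3",
        "utr3": "utr5",
    }
    other = {"+": "-", "-": "+"}
    for g in models:
        mirror = GeneModel(
            gene_id=g.gene_id, transcript_id=g.transcript_id, chrom=g.chrom,
            strand=other[g.strand],
            start=L + 1 - g.end, end=L + 1 - g.start,
            exons=tuple(sorted((L + 1 - e, L + 1 - s) for s, e in g.exons)),
            cds=tuple(sorted((L + 1 - e, L + 1 - s) for s, e in g.cds)),
        )
        flipped = GeneModel(
            gene_id=g.gene_id, transcript_id=g.transcript_id, chrom=g.chrom,
            strand=other[g.strand], start=g.start, end=g.end,
            exons=g.exons, cds=g.cds,
        )
        fwd_ann = Annotator([g])
        mir_ann = Annotator([mirror])
        flip_ann = Annotator([flipped])
        for pos in range(g.start - 5100, g.end + 5100, 37):
            if not 1 <= pos <= L or not 1 <= L + 1 - pos <= L:
                continue
            a = fwd_ann.annotate_position("chr1", pos)
            assert mir_ann.annotate_position("chr1", L + 1 - pos) == a, (
                g.transcript_id, pos)
            b = flip_ann.annotate_position("chr1", pos)
            assert b == swap.get(a, a), (g.transcript_id, pos)


def test_every_locus_gets_exactly_one_category(small_dataset):
    models = small_dataset["reference"].gene_models
    results = Annotator(models).annotate_all(small_dataset["matrix"].loci)
    assert len(results) == small_dataset["matrix"].n_loci
    assert all(r.category in im.annotate.CATEGORIES for r in results)


class TestCategorySummary:
    def test_simple_percentages(self):
        cats = ["intron", "intron", "exon", "intergenic"]
        results = [
            im.AnnotationResult(_locus("chr1", 10 * (i + 1)), c)
            for i, c in enumerate(cats)
        ]
        df = summarize_categories(results).set_index("category")
        assert df.loc["intron", "percentage"] == 50.00
        assert df.loc["exon", "percentage"] == 25.00
        assert df.loc["intergenic", "percentage"] == 25.00
        assert df["count"].sum() == 4

    def test_single_category_is_one_hundred_percent(self):
        results = [im.AnnotationResult(_locus("chr1", 10), "intron")]
        df = summarize_categories(results).set_index("category")
        assert df.loc["intron", "percentage"] == 100.0

    def test_empty_input_empty_table(self):
        assert summarize_categories([]).empty

    def test_percentages_sum_to_one_hundred(self, small_dataset):
        models = small_dataset["reference"].gene_models
        results = Annotator(models).annotate_all(small_dataset["matrix"].loci)
        df = summarize_categories(results)
        assert abs(df["percentage"].sum() - 100.0) <= 0.01 + 1e-9
        assert df["count"].sum() == len(results)


def test_gff3_round_trip_gene_models(small_dataset):
    loaded = load_gene_models(small_dataset["paths"]["gff3"])
    original = {g.transcript_id: g for g in small_dataset["reference"].gene_models}
    assert len(loaded) == len(original)
    for g in loaded:
        o = original[g.transcript_id]
        assert (g.chrom, g.strand, g.start, g.end) == (o.chrom, o.strand, o.start, o.end)
        assert g.exons == o.exons
        assert g.cds == o.cds
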