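"""Genomic-context annotation of InDel loci.

Each locus is assigned exactly one of twelve categories from a GFF3 gene
annotation: downstream, exon, intergenic, intron, none, splice-site
acceptor/donor/region, transcript, upstream, 3'UTR, 5'UTR. The
conventions follow the de-facto standard of snpEff-style annotators and
are configurable:

* splice donor / acceptor: first / last 2 bp of an intron, by transcript
  strand;
* splice-site region: 3–8 bp into an intron, or the 3 exonic bp flanking
  an exon–intron junction;
* upstream / downstream: 5 kb windows beyond the transcript span,
  strand-aware;
* 5'/3' UTR: exonic positions outside the CDS span, 5' vs 3' by strand;
* transcript: inside the span but with no exon structure to resolve
  against;
* none: unannotatable records (e.g. a chromosome absent from the GFF) in
  lenient mode.

A position overlapped by several transcripts gets the highest-precedence
category (most specific wins). An InDel spanning two classes is
classified by its VCF anchor position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, IndelLocus
from .errors import DataError

logger = logging.getLogger(__name__)

#: Highest precedence first.
CATEGORY_PRECEDENCE = (
    "splice_site_donor",
    "splice_site_acceptor",
    "splice_site_region",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "transcript",
    "upstream",
    "downstream",
    "intergenic",
    "none",
)
_RANK = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}

#: Table-ready category order (alphabetical, the conventional report order).
CATEGORIES = tuple(sorted(CATEGORY_PRECEDENCE))


@dataclass(frozen=True)
class AnnotationWindows:
    """Window sizes (bp) controlling the positional categories."""

    upstream: int = 5000
    downstream: int = 5000
    splice_site: int = 2  # donor/acceptor: first/last N bp of an intron
    splice_region_intron: tuple[int, int] = (3, 8)  # bp into the intron
    splice_region_exon: int = 3  # exonic bp flanking a junction

    def __post_init__(self) -> None:
        if min(self.upstream, self.downstream) < 0 or self.splice_site < 1:
            raise DataError("annotation windows must be non-negative")


@dataclass(frozen=True)
class AnnotationResult:
    locus: IndelLocus
    category: str


def load_gene_models(gff3_path: Path | str) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 into gene models."""
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        exons = tuple(
            sorted((f.start, f.end) for f in db.children(tx, featuretype="exon"))
        )
        cds = tuple(
            sorted((f.start, f.end) for f in db.children(tx, featuretype="CDS"))
        )
        parents = list(db.parents(tx, featuretype="gene"))
        models.append(
            GeneModel(
                gene_id=parents[0].id if parents else tx.id,
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                start=tx.start,
                end=tx.end,
                exons=exons,
                cds=cds,
            )
        )
    return models


def _classify_in_transcript(pos: int, gm: GeneModel, w: AnnotationWindows) -> str:
    """Category of a position inside the transcript span."""
    if not gm.exons:
        return "transcript"
    fwd = gm.strand == "+"
    in_exon = None
    for i, (s, e) in enumerate(gm.exons):
        if s <= pos <= e:
            in_exon = i
            break
    if in_exon is not None:
        s, e = gm.exons[in_exon]
        # exonic splice region: within N bp of an edge that touches an intron
        left_junction = in_exon > 0
        right_junction = in_exon < len(gm.exons) - 1
        if (left_junction and pos - s < w.splice_region_exon) or (
            right_junction and e - pos < w.splice_region_exon
        ):
            return "splice_site_region"
        if gm.cds:
            cds_lo = gm.cds[0][0]
            cds_hi = gm.cds[-1][1]
            in_cds = any(cs <= pos <= ce for cs, ce in gm.cds)
            if not in_cds:
                if pos < cds_lo:
                    return "utr5" if fwd else "utr3"
                if pos > cds_hi:
                    return "utr3" if fwd else "utr5"
        return "exon"
    # intronic
    for s, e in gm.introns:
        if s <= pos <= e:
            d_left = pos - s + 1  # 1-based offset from the genomic-left end
            d_right = e - pos + 1
            d_donor, d_acceptor = (d_left, d_right) if fwd else (d_right, d_left)
            if d_donor <= w.splice_site:
                return "splice_site_donor"
            if d_acceptor <= w.splice_site:
                return "splice_site_acceptor"
            lo, hi = w.splice_region_intron
            if lo <= d_donor <= hi or lo <= d_acceptor <= hi:
                return "splice_site_region"
            return "intron"
    # inside the span but in a gap the exon structure does not cover
    return "transcript"


def _classify_flank(pos: int, gm: GeneModel, w: AnnotationWindows) -> str | None:
    fwd = gm.strand == "+"
    if pos < gm.start:
        dist = gm.start - pos
        if fwd and dist <= w.upstream:
            return "upstream"
        if not fwd and dist <= w.downstream:
            return "downstream"
    elif pos > gm.end:
        dist = pos - gm.end
        if fwd and dist <= w.downstream:
            return "downstream"
        if not fwd and dist <= w.upstream:
            return "upstream"
    return None


class Annotator:
    """Indexes gene models per chromosome for fast positional queries.

    ``strict=True`` raises on a chromosome absent from the annotation;
    lenient mode (default) assigns ``none`` with a logged warning.
    """

    def __init__(
        self,
        gene_models: list[GeneModel],
        windows: AnnotationWindows = AnnotationWindows(),
        strict: bool = False,
    ) -> None:
        self.windows = windows
        self.strict = strict
        self._trees: dict[str, IntervalTree] = {}
        flank = max(windows.upstream, windows.downstream)
        for gm in gene_models:
            tree = self._trees.setdefault(gm.chrom, IntervalTree())
            # interval end is exclusive
            tree.addi(max(1, gm.start - flank), gm.end + flank + 1, gm)
        self._warned: set[str] = set()

    def annotate_position(self, chrom: str, pos: int) -> str:
        if chrom not in self._trees:
            if self.strict:
                raise DataError(f"chromosome {chrom!r} absent from the annotation")
            if chrom not in self._warned:
                logger.warning("chromosome %r absent from the annotation", chrom)
                self._warned.add(chrom)
            return "none"
        best = "intergenic"
        for iv in self._trees[chrom][pos]:
            gm: GeneModel = iv.data
            if gm.start <= pos <= gm.end:
                cat = _classify_in_transcript(pos, gm, self.windows)
            else:
                cat = _classify_flank(pos, gm, self.windows)
            if cat is not None and _RANK[cat] < _RANK[best]:
                best = cat
        return best

    def annotate(self, locus: IndelLocus) -> AnnotationResult:
        """Annotate one InDel by its VCF anchor position."""
        return AnnotationResult(locus, self.annotate_position(locus.chrom, locus.pos))

    def annotate_all(self, loci: list[IndelLocus]) -> list[AnnotationResult]:
        return [self.annotate(locus) for locus in loci]


def annotate(
    locus: IndelLocus,
    gene_models: list[GeneModel],
    windows: AnnotationWindows = AnnotationWindows(),
    strict: bool = False,
) -> AnnotationResult:
    """One-shot annotation of a single locus (builds a throwaway index)."""
    return Annotator(gene_models, windows, strict).annotate(locus)


def summarize_categories(results: list[AnnotationResult]) -> pd.DataFrame:
    """Category counts and percentages; percentages sum to 100 (+-0.01)."""
    if not results:
        return pd.DataFrame(columns=["category", "count", "percentage"])
    counts = pd.Series([r.category for r in results]).value_counts()
    df = pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [int(counts.get(c, 0)) for c in CATEGORIES],
        }
    )
    df["percentage"] = (100.0 * df["count"] / len(results)).round(2)
    return df


def results_to_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.locus.chrom,
                "pos": r.locus.pos,
                "ref": r.locus.ref,
                "alt": r.locus.alt,
                "category": r.category,
            }
            for r in results
        ],
        columns=["chrom", "pos", "ref", "alt", "category"],
    )
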