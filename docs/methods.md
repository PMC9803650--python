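# Methods

## The diagnostic condition

The unit of analysis is the biallelic InDel contrast at a VCF site.
Group A and group B (e.g. two sister taxa) are each represented by a set
of diploid samples; a locus is **diagnostic** when every called group-A
sample is homozygous for one allele and every called group-B sample is
homozygous for a *different* allele. This is the "fixed difference"
reading of the requirement that a marker be homozygous within each group
yet heterozygous between them: it refers to the groups being fixed for
different alleles — so that any inter-group cross is heterozygous — not
to any individual being heterozygous. It is the only reading consistent
with using the markers to detect F1 hybrids by their two-band patterns.

Missing genotypes: the default policy tolerates **zero** missing
genotypes per group (the strictest reading of within-group homozygosity)
and is configurable (`MissingPolicy.max_missing_per_group`). Above the
tolerance a locus is *indeterminate*, not non-diagnostic: absence of
data is not evidence of segregation. Half-calls (`0/.`) are treated as
fully missing, since one called allele cannot establish homozygosity.
The diagnostic set is monotone in the tolerance (tested).

Multiallelic sites are decomposed per ALT allele, keeping the record's
original allele indices, so an alt-vs-alt fixed contrast is recognised
naturally; its InDel length is the length difference between the two
fixed alleles. A fixed contrast between equal-length alleles is not an
InDel and is classified non-diagnostic. Diagnostic calls are ordered by
InDel length descending (ties by chromosome, then position — a total
order), reflecting that long InDels are selected first for gel scoring.

## Annotation conventions

The twelve genomic-context categories follow snpEff-style conventions,
all configurable via `AnnotationWindows`:

| category | definition (defaults) |
|---|---|
| splice donor / acceptor | first / last 2 bp of an intron, by transcript strand |
| splice-site region | 3–8 bp into an intron, or the 3 exonic bp flanking a junction |
| utr5 / utr3 | exonic positions outside the CDS span, 5′/3′ by strand |
| exon / intron | by exon structure |
| transcript | inside the span, no finer structure available |
| upstream / downstream | 5 kb windows beyond the transcript span, strand-aware |
| intergenic | nothing within any window |
| none | unannotatable (e.g. chromosome absent from the GFF) in lenient mode |

A position under several transcripts takes the highest-precedence
(most specific) category: donor > acceptor > region > utr5 > utr3 >
exon > intron > transcript > upstream > downstream > intergenic. The
equal-specificity pairs need a deterministic order; donor-before-
acceptor and upstream-before-downstream were chosen. Because these
tie-breaks are direction-asymmetric, strand symmetry (mirror the genome
and flip strands ⇒ identical categories; flip a strand in place ⇒
donor↔acceptor, upstream↔downstream, utr5↔utr3) holds per transcript
and is tested per transcript. An InDel spanning two classes is
classified by its VCF anchor position — a single deterministic
coordinate, and a known limitation for long deletions. For an unknown
chromosome the lenient mode reports `none` (the report category exists
precisely for unannotatable records); strict mode raises instead.

## Primer search

The designer is self-contained (no external primer tool): it enumerates
every primer placement in the flanks and keeps, per locus, the pair
whose **reference-allele amplicon** is closest to the midpoint of the
size window (275 bp for 150–400), tie-broken by smaller amplicon, then
leftmost forward primer, then shortest primers. Both allele amplicons
must satisfy the size bounds; the InDel must lie strictly between the
primer binding sites, which is what forces the amplicon-size difference
to equal the InDel length. Primer length defaults to 18–27 bp, and a
primer is rejected if its binding site recurs within ±10 kb of the
locus (a local uniqueness proxy; genome-wide specificity screening is
out of scope). Loci with infeasible flanks (e.g. contig edges) are
skipped with a logged reason. The implementation reduces the pair
search to a per-start binary search over reverse-primer ends; tests
verify exact agreement with a brute-force enumeration over all pairs.

Melting temperature defaults to the two-state nearest-neighbor model
with the unified Allawi & SantaLucia (1997) stack parameters,
duplex-initiation terms, the SantaLucia (1998) entropy salt correction
(0.368 · (N−1) · ln[Na⁺], 50 mM Na⁺) and 25 nM strand concentrations;
the parameter table is in `design.py`. The table is reverse-complement
symmetric, so a reverse primer scores identically to its top-strand
binding site — which the vectorised search exploits. Tests require
agreement with an independent implementation of the same published
parameter set to 0.5 °C (observed: exact). The Wallace rule
(2·AT + 4·GC) is kept as a hand-checkable alternative.

Tiers partition the designable lengths — (> 50, (40, 50], (34, 40],
(20, 34]) — so tier counts sum to the candidate total; the "> 40"-style
labels name each tier by its lower bound.

## Gel and dropout model

Agarose resolvability is a single floor: bands closer than
`min_resolvable_diff` (default 20 bp on a 2 % gel, roughly the smallest
difference confidently read by eye) co-migrate and are reported as one
band at the midpoint size. This deliberately replaces migration physics
with the one decision that matters for marker selection. Allelic
dropout is modeled per band, independently, with probability *d* in
heterozygotes only — homozygotes have a single amplifiable product whose
loss would be a PCR failure, not dropout. The single-band frequency
among heterozygotes is therefore 2 d (1 − d) and the no-band frequency
d², both tested against exact binomial intervals. Band-pattern calling
inverts prediction exactly in the noise-free case (round-trip tested);
a single band where the pedigree implies a heterozygote is flagged
`dropout_suspect` — the pattern cannot distinguish stochastic dropout
from a null allele, so the module flags rather than adjudicates.

A marker panel is scored per marker: accepted only with zero miscalls,
zero dropout suspects and zero fails over all tested individuals. This
reproduces the qualitative validation logic in which one marker whose
F1s sometimes showed a single parental band had to be discarded while
its dropout-free companions were kept. Sequence-level confirmation of
amplified products is represented only as an externally supplied
validation flag; chromatogram processing is out of scope.

## Synthetic data

The generator emulates the essential structure of a two-taxon
whole-genome resequencing comparison: two groups of diploid samples
(default 7 + 7), a reference belonging to group B — so diagnostic sites
are ALT-homozygous in group A and REF-homozygous in group B, which
reproduces the characteristic ref-homo/alt-homo asymmetry between the
groups' per-sample summaries — plus within-group polymorphic InDels
(shared and private), per-cell genotype missingness, and Mendelian F1
crosses with optional per-band dropout downstream.

Defaults and why:

- **InDel lengths uniform on [5, 60] bp.** Only the selection thresholds
  (> 20 / > 34 / > 40 / > 50 bp) are known design inputs; a uniform
  spectrum across them populates every tier boundary. It is a stand-in,
  not an estimate of any empirical length distribution.
- **Variant spacing ≥ 500 bp** keeps each 150–400 bp amplicon over
  exactly one planted InDel, so truth evaluation is unambiguous.
- **Gene density 10 / Mb**, single-transcript genes with 2–5 exons,
  introns 200–900 bp and CDS trimmed into the terminal exons: enough
  anatomy to exercise every annotation category, with no claim of
  realism beyond that.
- Polymorphic sites are constructed with at least one heterozygote per
  segregating group, so by construction no polymorphic site can satisfy
  the diagnostic predicate — recovery tests are exact, not statistical.
- Missingness is i.i.d. per genotype cell (`./.` in the VCF); real
  missingness is depth- and locus-correlated, which this does not model.

Everything is keyed on a single integer seed through stage-specific
`numpy` generator streams: identical configs give byte-identical
FASTA/VCF/GFF3/TSV outputs (tested, and re-verified on every
acceptance run). What passing tests on this generator shows is that the
pipeline's logic is sound under its stated model — fixed differences
are recovered exactly, designed amplicons obey the codominant geometry,
F1s are 100 % heterozygous at accepted markers; it does not show
robustness to alignment artefacts, variant-calling error, or primer-site
mutations in real genomes (the leading causes of marker attrition in
practice).

## Problem sizes

The test suite and the acceptance script run the study design at
50 planted diagnostic + 200 polymorphic InDels over 7 + 7 samples on
two 500 kb chromosomes, with an additional 100-simulation design sweep
at 3 + 4 variants each; these sizes exercise every code path while
keeping a full run in seconds. The scan and designer are linear in loci
and were not profiled beyond that scale.

## Known limitations

- Anchor-position annotation misclassifies InDels spanning a feature
  boundary toward their left edge.
- Primer thermodynamics cover Tm only; dimers, hairpins and 3′-end
  stability are not modeled.
- Alt-vs-alt fixed contrasts are detected by the scan but not designable
  as markers (the designer requires the reference allele in the
  contrast); they are reported as skipped.
- The gel model has no size-dependent resolution curve; a constant floor
  approximates a 2 % gel in the 150–400 bp range only.
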