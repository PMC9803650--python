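"""Shared domain types.

The unit of analysis is the InDel locus: a VCF site whose REF and ALT
alleles differ in length. Multi-sample diploid genotypes at these loci,
together with a sample-to-group assignment, form a
:class:`GroupedGenotypeMatrix` — the substrate for fixed-difference
scanning between two population groups (e.g. two sister taxa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError

#: Sentinel for a missing allele in the genotype array.
MISSING = -1


@dataclass(frozen=True)
class IndelLocus:
    """One InDel site, decomposed to a single focal ALT allele.

    ``alts`` keeps every ALT of the originating VCF record so that genotype
    allele indices remain the record's own indices; ``alt_index`` (1-based
    allele index) names the focal ALT of this decomposed locus.
    """

    chrom: str
    pos: int  # 1-based VCF position
    ref: str
    alts: tuple[str, ...]
    alt_index: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"VCF positions are 1-based; got {self.pos}")
        if not (1 <= self.alt_index <= len(self.alts)):
            raise DataError(
                f"alt_index {self.alt_index} out of range for {len(self.alts)} alts"
            )
        if self.alt == self.ref:
            raise DataError(f"{self.chrom}:{self.pos} ALT equals REF")
        if len(self.alt) == len(self.ref):
            raise DataError(
                f"{self.chrom}:{self.pos} REF/ALT of equal length: site is not an InDel"
            )

    @property
    def alt(self) -> str:
        return self.alts[self.alt_index - 1]

    @property
    def indel_length_bp(self) -> int:
        """Absolute REF/ALT length difference for the focal ALT."""
        return abs(len(self.alt) - len(self.ref))

    @property
    def indel_type(self) -> str:
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    def allele(self, index: int) -> str:
        """Allele string for a genotype allele index (0 = REF)."""
        return self.ref if index == 0 else self.alts[index - 1]


@dataclass
class GroupedGenotypeMatrix:
    """Per-sample diploid genotypes at InDel loci plus the group map.

    ``gt`` has shape ``(n_loci, n_samples, 2)`` with allele indices
    (0 = REF) and :data:`MISSING` for missing alleles. Half-calls are
    stored fully missing — a single called allele cannot establish
    homozygosity.
    """

    loci: list[IndelLocus]
    samples: list[str]
    group_of: dict[str, str]
    gt: np.ndarray
    groups: tuple[str, str] = field(default=("A", "B"))

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int16)
        if self.gt.shape != (len(self.loci), len(self.samples), 2):
            raise DataError(
                f"genotype array shape {self.gt.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        missing = [s for s in self.samples if s not in self.group_of]
        if missing:
            raise ConfigurationError(
                f"samples absent from the group table: {', '.join(missing)}"
            )
        labels = set(self.group_of[s] for s in self.samples)
        if labels != set(self.groups):
            raise ConfigurationError(
                f"group labels {sorted(labels)} do not match declared groups {self.groups}"
            )
        for g in self.groups:
            if not any(self.group_of[s] == g for s in self.samples):
                raise ConfigurationError(f"group {g!r} has no samples")
        for i, locus in enumerate(self.loci):
            n_alleles = 1 + len(locus.alts)
            if self.gt[i].max() >= n_alleles:
                raise DataError(
                    f"{locus.chrom}:{locus.pos} genotype allele index "
                    f"{int(self.gt[i].max())} >= {n_alleles} alleles"
                )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_columns(self, group: str) -> list[int]:
        """Column indices of the samples belonging to ``group``."""
        return [j for j, s in enumerate(self.samples) if self.group_of[s] == group]


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model: transcript span, exons, optional CDS.

    Coordinates are 1-based inclusive. Exons must be non-overlapping,
    ordered, and inside the transcript span; CDS intervals must lie within
    exons.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DataError(f"{self.transcript_id}: strand must be + or -")
        if not (1 <= self.start <= self.end):
            raise DataError(f"{self.transcript_id}: bad transcript span")
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end or e < s or s < self.start or e > self.end:
                raise DataError(
                    f"{self.transcript_id}: exons must be ordered, "
                    "non-overlapping and within the transcript span"
                )
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise DataError(f"{self.transcript_id}: CDS interval outside exons")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intervals between consecutive exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] - self.exons[i][1] > 1
        )
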