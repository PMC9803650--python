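"""Synthetic two-group resequencing data.

Generates toy reference genomes with gene models, plants between-group
fixed (diagnostic) and within-group polymorphic InDels into a diploid
genotype matrix for two groups of samples, simulates F1 crosses, and
writes everything out as FASTA/VCF/GFF3/TSV so the downstream pipeline is
testable without any real sequencing data.

The default configuration mirrors the study design this emulates: seven
samples per group, with the reference assembly belonging to group B (so
the reference carries group-B alleles at every diagnostic site, which
reproduces the characteristic Ref-homo/Alt-homo asymmetry between the two
groups' per-sample summaries). InDel lengths default to uniform on
[5, 60] bp so every marker-design tier boundary (>20, >34, >40, >50 bp)
is populated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from pyfaidx import Faidx

from .core import MISSING, GeneModel, GroupedGenotypeMatrix, IndelLocus
from .errors import ConfigurationError, LocusMismatchError, SizingError

_BASES = np.array(list("ACGT"))

# Gene-structure geometry (bp). Fixed, not exposed: the annotation stages
# only need plausible exon/intron/UTR anatomy, not a realistic gene model.
_EXON_RANGE = (120, 300)
_INTRON_RANGE = (200, 900)
_N_EXON_RANGE = (2, 5)
_UTR_TRIM = (30, 90)  # terminal-exon bp left outside the CDS
_MAX_GENE_SPAN = _N_EXON_RANGE[1] * _EXON_RANGE[1] + (_N_EXON_RANGE[1] - 1) * _INTRON_RANGE[1]


@dataclass(frozen=True)
class IndelLengthSpec:
    """Length spectrum for planted InDels: uniform on [min_bp, max_bp]."""

    min_bp: int = 5
    max_bp: int = 60
    shape: str = "uniform"

    def __post_init__(self) -> None:
        if self.min_bp < 1:
            raise ConfigurationError("indel length min_bp must be >= 1")
        if self.max_bp < self.min_bp:
            raise ConfigurationError("indel length max_bp must be >= min_bp")
        if self.shape != "uniform":
            raise ConfigurationError(f"unknown indel length shape {self.shape!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(self.min_bp, self.max_bp + 1, size=n)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_group_a: int = 7
    n_group_b: int = 7
    n_diagnostic: int = 50
    n_shared_polymorphic: int = 100
    n_private_polymorphic: int = 100
    indel_length: IndelLengthSpec = field(default_factory=IndelLengthSpec)
    missing_rate: float = 0.0
    dropout_rate: float = 0.0
    gene_density: float = 10.0  # genes per Mb
    variant_spacing: int = 500  # min bp between planted variants
    edge_margin: int = 600  # keep variants this far from contig ends

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length", "n_group_a", "n_group_b",
            "n_diagnostic", "n_shared_polymorphic", "n_private_polymorphic",
            "variant_spacing", "edge_margin",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("missing_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.gene_density < 0:
            raise ConfigurationError("gene_density must be >= 0")
        if self.n_chromosomes > 0 and self.chrom_length < 1:
            raise ConfigurationError("chrom_length must be >= 1")

    @property
    def n_variants(self) -> int:
        return self.n_diagnostic + self.n_shared_polymorphic + self.n_private_polymorphic

    @property
    def sample_names(self) -> tuple[list[str], list[str]]:
        a = [f"A{i + 1:02d}" for i in range(self.n_group_a)]
        b = [f"B{i + 1:02d}" for i in range(self.n_group_b)]
        return a, b


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    cls: str  # diagnostic | shared_polymorphic | private_polymorphic
    group_a_allele: int | None
    group_b_allele: int | None
    indel_length_bp: int


@dataclass
class TruthTable:
    """Planted-variant ground truth: one record per emitted VCF line."""

    records: list[TruthRecord]

    def of_class(self, cls: str) -> list[TruthRecord]:
        return [r for r in self.records if r.cls == cls]

    def positions(self, cls: str | None = None) -> set[tuple[str, int]]:
        recs = self.records if cls is None else self.of_class(cls)
        return {(r.chrom, r.pos) for r in recs}


@dataclass
class Reference:
    """In-memory reference genome: chromosome sequences plus gene models."""

    sequences: dict[str, str]
    gene_models: list[GeneModel]

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # Stage-keyed streams keep each step reproducible independently of the
    # amount of randomness the previous steps consumed.
    return np.random.default_rng([config.seed, stage])


def _simulate_gene(rng: np.random.Generator, chrom: str, start: int,
                   max_end: int, idx: int) -> GeneModel:
    n_exons = int(rng.integers(*_N_EXON_RANGE, endpoint=True))
    exons: list[tuple[int, int]] = []
    pos = start
    for i in range(n_exons):
        if i > 0:
            pos += int(rng.integers(*_INTRON_RANGE, endpoint=True))
        elen = int(rng.integers(*_EXON_RANGE, endpoint=True))
        exons.append((pos, pos + elen - 1))
        pos = exons[-1][1] + 1
    if exons[-1][1] > max_end:
        raise SizingError("gene model exceeds its slot")
    strand = "+" if rng.random() < 0.5 else "-"
    # CDS trims into the terminal exons so both UTRs exist.
    trim5 = int(rng.integers(*_UTR_TRIM, endpoint=True))
    trim3 = int(rng.integers(*_UTR_TRIM, endpoint=True))
    cds_lo = exons[0][0] + (trim5 if strand == "+" else trim3)
    cds_hi = exons[-1][1] - (trim3 if strand == "+" else trim5)
    cds = tuple(
        (max(s, cds_lo), min(e, cds_hi)) for s, e in exons if e >= cds_lo and s <= cds_hi
    )
    return GeneModel(
        gene_id=f"gene{idx:04d}",
        transcript_id=f"tx{idx:04d}",
        chrom=chrom,
        strand=strand,
        start=exons[0][0],
        end=exons[-1][1],
        exons=tuple(exons),
        cds=cds,
    )


def simulate_reference(config: SimulationConfig) -> Reference:
    """Random chromosomes (uniform base composition, GC ~= 0.5) with
    non-overlapping single-transcript gene models on both strands.

    Genes are laid out in equal slots along each chromosome, one gene per
    slot at a random offset, which guarantees non-overlap and determinism.

    Raises :class:`SizingError` when ``chrom_length`` cannot host the
    requested ``gene_density``.
    """
    rng = _rng(config, stage=1)
    sequences: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    gidx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = rng.choice(_BASES, size=config.chrom_length)
        sequences[chrom] = "".join(seq)
        n_genes = int(round(config.gene_density * config.chrom_length / 1e6))
        if n_genes == 0:
            continue
        slot = config.chrom_length // n_genes
        if slot < _MAX_GENE_SPAN + 2:
            raise SizingError(
                f"chrom_length {config.chrom_length} too small for {n_genes} genes: "
                f"each gene needs a slot of >= {_MAX_GENE_SPAN + 2} bp, got {slot}"
            )
        for g in range(n_genes):
            gidx += 1
            slot_start = g * slot + 1
            offset = int(rng.integers(0, slot - _MAX_GENE_SPAN - 1))
            gene_models.append(
                _simulate_gene(rng, chrom, slot_start + offset, slot_start + slot - 1, gidx)
            )
    return Reference(sequences=sequences, gene_models=gene_models)


def _variant_positions(rng: np.random.Generator, config: SimulationConfig) -> list[tuple[str, int]]:
    """Anchor positions spaced >= variant_spacing, away from contig ends."""
    positions: list[tuple[str, int]] = []
    # Reserve max indel length after each anchor so deletions fit the contig.
    tail = config.indel_length.max_bp + 1
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        lo = config.edge_margin + 1
        hi = config.chrom_length - config.edge_margin - tail
        pos = lo
        while pos <= hi:
            jitter = int(rng.integers(0, config.variant_spacing // 2 + 1))
            p = pos + jitter
            if p > hi:
                break
            positions.append((chrom, p))
            pos = p + config.variant_spacing
    if len(positions) < config.n_variants:
        raise SizingError(
            f"requested {config.n_variants} variants but only {len(positions)} "
            f"positions available at spacing {config.variant_spacing} bp"
        )
    take = rng.choice(len(positions), size=config.n_variants, replace=False)
    return [positions[i] for i in sorted(take)]


def _random_insertion(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _segregating_genotypes(rng: np.random.Generator, n: int) -> np.ndarray:
    """n diploid genotypes over alleles {0,1} with at least one heterozygote,
    so the group can never look fixed."""
    gt = rng.integers(0, 2, size=(n, 2))
    het = int(rng.integers(0, n))
    gt[het] = (0, 1)
    return gt


def plant_variants(reference: Reference, config: SimulationConfig) -> tuple[GroupedGenotypeMatrix, TruthTable]:
    """Plant diagnostic and polymorphic InDels into a two-group genotype set.

    Diagnostic sites are fixed for the ALT allele in every group-A sample
    and for the REF allele in every group-B sample (the reference carries
    the group-B allele). Shared-polymorphic sites segregate in both groups;
    private-polymorphic sites segregate in exactly one. Genotype cells are
    then masked to missing at ``missing_rate``. VCF conventions apply:
    1-based anchor position, REF/ALT left-anchored with one shared leading
    base.
    """
    rng = _rng(config, stage=2)
    names_a, names_b = config.sample_names
    samples = names_a + names_b
    group_of = {s: "A" for s in names_a} | {s: "B" for s in names_b}
    n = config.n_variants

    anchors = _variant_positions(rng, config)
    lengths = config.indel_length.draw(rng, n)
    is_insertion = rng.random(n) < 0.5
    classes = (
        ["diagnostic"] * config.n_diagnostic
        + ["shared_polymorphic"] * config.n_shared_polymorphic
        + ["private_polymorphic"] * config.n_private_polymorphic
    )
    rng.shuffle(classes)

    loci: list[IndelLocus] = []
    records: list[TruthRecord] = []
    gt = np.zeros((n, len(samples), 2), dtype=np.int16)
    na, nb = config.n_group_a, config.n_group_b

    for i, ((chrom, pos), length, ins, cls) in enumerate(
        zip(anchors, lengths, is_insertion, classes)
    ):
        seq = reference[chrom]
        anchor = seq[pos - 1]
        if ins:
            ref_allele, alt_allele = anchor, anchor + _random_insertion(rng, int(length))
        else:
            ref_allele, alt_allele = seq[pos - 1 : pos + int(length)], anchor
        loci.append(IndelLocus(chrom=chrom, pos=pos, ref=ref_allele, alts=(alt_allele,)))

        ga = gb = None
        if cls == "diagnostic":
            gt[i, :na] = 1
            gt[i, na:] = 0
            ga, gb = 1, 0
        elif cls == "shared_polymorphic":
            gt[i, :na] = _segregating_genotypes(rng, na)
            gt[i, na:] = _segregating_genotypes(rng, nb)
        else:  # private_polymorphic
            if rng.random() < 0.5:
                gt[i, :na] = _segregating_genotypes(rng, na)
                gt[i, na:] = 0
            else:
                gt[i, :na] = 0
                gt[i, na:] = _segregating_genotypes(rng, nb)
        records.append(
            TruthRecord(
                chrom=chrom, pos=pos, ref=ref_allele, alt=alt_allele, cls=cls,
                group_a_allele=ga, group_b_allele=gb, indel_length_bp=int(length),
            )
        )

    if config.missing_rate > 0:
        mask = rng.random((n, len(samples))) < config.missing_rate
        gt[mask] = MISSING

    matrix = GroupedGenotypeMatrix(
        loci=loci, samples=samples, group_of=group_of, gt=gt, groups=("A", "B")
    )
    return matrix, TruthTable(records=records)


def simulate_f1(
    parent_a: tuple[list[IndelLocus], np.ndarray],
    parent_b: tuple[list[IndelLocus], np.ndarray],
    seed: int,
    n_offspring: int = 1,
) -> np.ndarray:
    """Mendelian cross: each offspring receives one allele drawn uniformly
    from each parent at every locus.

    Parents are ``(loci, genotypes)`` pairs with genotypes of shape
    ``(n_loci, 2)``. At loci where the parents are homozygous for different
    alleles every offspring is heterozygous with certainty.

    Raises :class:`LocusMismatchError` if the locus lists differ and
    :class:`~indelmark.errors.DataError` if a parent genotype is missing.
    """
    loci_a, gt_a = parent_a
    loci_b, gt_b = parent_b
    if loci_a != loci_b:
        raise LocusMismatchError("parents do not share the same locus set")
    gt_a = np.asarray(gt_a)
    gt_b = np.asarray(gt_b)
    if (gt_a == MISSING).any() or (gt_b == MISSING).any():
        raise LocusMismatchError("parents must have called genotypes at every locus")
    rng = np.random.default_rng(seed)
    n_loci = len(loci_a)
    out = np.empty((n_offspring, n_loci, 2), dtype=np.int16)
    for k in range(n_offspring):
        pick_a = rng.integers(0, 2, size=n_loci)
        pick_b = rng.integers(0, 2, size=n_loci)
        out[k, :, 0] = gt_a[np.arange(n_loci), pick_a]
        out[k, :, 1] = gt_b[np.arange(n_loci), pick_b]
    return out if n_offspring > 1 else out[0]


# ---------------------------------------------------------------------------
# file output


def write_fasta(reference: Reference, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    Faidx(str(path))  # writes the .fai index alongside


def write_gff3(reference: Reference, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in reference.sequences.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for gm in reference.gene_models:
            base = f"{gm.chrom}\tindelmark\t"
            tail = f"\t.\t{gm.strand}\t.\t"
            fh.write(f"{base}gene\t{gm.start}\t{gm.end}{tail}ID={gm.gene_id}\n")
            fh.write(
                f"{base}mRNA\t{gm.start}\t{gm.end}{tail}"
                f"ID={gm.transcript_id};Parent={gm.gene_id}\n"
            )
            for j, (s, e) in enumerate(gm.exons, 1):
                fh.write(
                    f"{base}exon\t{s}\t{e}{tail}"
                    f"ID={gm.transcript_id}.exon{j};Parent={gm.transcript_id}\n"
                )
            for j, (s, e) in enumerate(gm.cds, 1):
                fh.write(
                    f"{base}CDS\t{s}\t{e}\t.\t{gm.strand}\t0\t"
                    f"ID={gm.transcript_id}.cds;Parent={gm.transcript_id}\n"
                )


def write_vcf(matrix: GroupedGenotypeMatrix, reference: Reference, path: Path) -> None:
    """VCF v4.2 with GT-only FORMAT; missing genotypes written as ``./.``."""
    header = pysam.VariantHeader()
    for chrom, seq in reference.sequences.items():
        header.contigs.add(chrom, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.samples:
        header.add_sample(s)
    order = sorted(
        range(len(matrix.loci)),
        key=lambda i: (matrix.loci[i].chrom, matrix.loci[i].pos),
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in order:
            locus = matrix.loci[i]
            rec = vcf.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                alleles=(locus.ref, *locus.alts),
            )
            for j, s in enumerate(matrix.samples):
                a0, a1 = (int(x) for x in matrix.gt[i, j])
                rec.samples[s]["GT"] = (
                    (None, None) if MISSING in (a0, a1) else (a0, a1)
                )
            vcf.write(rec)


def write_groups_tsv(matrix: GroupedGenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in matrix.samples:
            fh.write(f"{s}\t{matrix.group_of[s]}\n")


def write_truth_tsv(truth: TruthTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tclass\tgroup_a_allele\tgroup_b_allele\tindel_length_bp\n"
        )
        for r in truth.records:
            ga = "." if r.group_a_allele is None else r.group_a_allele
            gb = "." if r.group_b_allele is None else r.group_b_allele
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.cls}\t{ga}\t{gb}\t"
                f"{r.indel_length_bp}\n"
            )


def write_outputs(
    matrix: GroupedGenotypeMatrix,
    truth: TruthTable,
    reference: Reference,
    out_dir: Path | str,
) -> dict[str, Path]:
    """Write the full synthetic dataset; returns the emitted file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "reference.fa",
        "gff3": out / "genes.gff3",
        "vcf": out / "indels.vcf",
        "groups": out / "groups.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(reference, paths["fasta"])
    write_gff3(reference, paths["gff3"])
    write_vcf(matrix, reference, paths["vcf"])
    write_groups_tsv(matrix, paths["groups"])
    write_truth_tsv(truth, paths["truth"])
    return paths


def simulate_dataset(config: SimulationConfig, out_dir: Path | str | None = None):
    """Convenience: reference + planted variants (+ files when ``out_dir``)."""
    reference = simulate_reference(config)
    matrix, truth = plant_variants(reference, config)
    paths = write_outputs(matrix, truth, reference, out_dir) if out_dir else None
    return reference, matrix, truth, paths


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain dict (e.g. YAML)."""
    d = dict(d)
    if "indel_length" in d and isinstance(d["indel_length"], dict):
        d["indel_length"] = IndelLengthSpec(**d["indel_length"])
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation options: {sorted(unknown)}")
    return SimulationConfig(**d)
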