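"""Fixed-difference (diagnostic) InDel scanning.

A locus is *diagnostic* between two groups when every non-missing sample
of group A is homozygous for one allele and every non-missing sample of
group B is homozygous for a different allele — so that any inter-group
cross is heterozygous at the locus. This module loads a multi-sample
InDel VCF plus a sample-to-group table, classifies each locus under a
configurable missingness policy, and emits the diagnostic set sorted by
InDel length, longest first (the order in which gel-resolvable marker
candidates are picked). It also produces per-sample homozygosity
summaries (reference-homozygous / alternate-homozygous / heterozygous /
missing counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import MISSING, GroupedGenotypeMatrix, IndelLocus
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

STATUS_DIAGNOSTIC = "diagnostic"
STATUS_NON_DIAGNOSTIC = "non_diagnostic"
STATUS_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class MissingPolicy:
    """Missing-genotype tolerance for a diagnostic call.

    ``max_missing_per_group`` is the largest number of missing genotypes
    tolerated in each group; with more, the locus is *indeterminate*
    rather than non-diagnostic. The default of 0 is the strictest reading
    of "homozygous within the groups". A group with no called genotypes at
    all is always indeterminate.
    """

    max_missing_per_group: int = 0

    def __post_init__(self) -> None:
        if self.max_missing_per_group < 0:
            raise ConfigurationError("max_missing_per_group must be >= 0")


@dataclass(frozen=True)
class DiagnosticCall:
    locus: IndelLocus
    status: str
    group_a_allele: int | None = None
    group_b_allele: int | None = None
    n_missing_a: int = 0
    n_missing_b: int = 0

    @property
    def contrast_length_bp(self) -> int | None:
        """Length difference between the two fixed alleles."""
        if self.status != STATUS_DIAGNOSTIC:
            return None
        a = self.locus.allele(self.group_a_allele)
        b = self.locus.allele(self.group_b_allele)
        return abs(len(a) - len(b))


def _read_groups(groups_path: Path | str) -> tuple[dict[str, str], tuple[str, str]]:
    df = pd.read_csv(groups_path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ConfigurationError(
            f"{groups_path}: expected two columns (sample id, group), got {cols}"
        )
    sample_col, group_col = cols[0], cols[1]
    if df[sample_col].duplicated().any():
        dup = df.loc[df[sample_col].duplicated(), sample_col].tolist()
        raise ConfigurationError(f"{groups_path}: duplicated samples {dup}")
    group_of = dict(zip(df[sample_col], df[group_col]))
    labels = list(dict.fromkeys(df[group_col]))  # first-appearance order
    if len(labels) != 2:
        raise ConfigurationError(
            f"{groups_path}: expected exactly 2 group labels, got {labels}"
        )
    return group_of, (labels[0], labels[1])


def _is_symbolic(allele: str) -> bool:
    return any(c in allele for c in "<>[]*.") or allele == ""


def load_matrix(vcf_path: Path | str, groups_path: Path | str) -> GroupedGenotypeMatrix:
    """Read an InDel VCF and a group table into a genotype matrix.

    Only InDel alleles are retained: SNP alts and symbolic/structural
    alleles are skipped (a count is logged). Multiallelic records are
    decomposed into one locus per InDel alt; each decomposed locus keeps
    the record's full allele list so genotype indices stay unchanged.
    Half-calls (e.g. ``0/.``) are stored as missing.
    """
    group_of, groups = _read_groups(groups_path)
    loci: list[IndelLocus] = []
    rows: list[np.ndarray] = []
    n_skipped_sites = 0
    try:
        vcf_in = pysam.VariantFile(str(vcf_path))
    except (ValueError, OSError) as e:
        raise DataError(f"cannot parse {vcf_path} as VCF: {e}") from e
    with vcf_in as vcf:
        samples = list(vcf.header.samples)
        ungrouped = [s for s in samples if s not in group_of]
        if ungrouped:
            raise ConfigurationError(
                f"VCF samples absent from the group table: {', '.join(ungrouped)}"
            )
        for rec in vcf:
            alts = tuple(rec.alts or ())
            indel_alts = [
                k + 1
                for k, alt in enumerate(alts)
                if not _is_symbolic(alt)
                and not _is_symbolic(rec.ref)
                and len(alt) != len(rec.ref)
            ]
            if not indel_alts:
                n_skipped_sites += 1
                continue
            row = np.full((len(samples), 2), MISSING, dtype=np.int16)
            for j, s in enumerate(samples):
                gtv = rec.samples[s].get("GT", (None, None))
                if gtv is None or len(gtv) != 2 or None in gtv:
                    continue  # half-calls and haploid calls treated as missing
                row[j] = gtv
            for k in indel_alts:
                loci.append(
                    IndelLocus(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=alts, alt_index=k
                    )
                )
                rows.append(row)
    if n_skipped_sites:
        logger.info("skipped %d non-InDel VCF records", n_skipped_sites)
    gt = np.stack(rows) if rows else np.zeros((0, len(samples), 2), dtype=np.int16)
    return GroupedGenotypeMatrix(
        loci=loci, samples=samples, group_of=group_of, gt=gt, groups=groups
    )


def _group_state(gt_rows: np.ndarray, max_missing: int):
    """(fixed allele or None, n_missing, indeterminate?) for one group."""
    is_missing = (gt_rows == MISSING).any(axis=1)
    n_missing = int(is_missing.sum())
    called = gt_rows[~is_missing]
    if n_missing > max_missing or len(called) == 0:
        return None, n_missing, True
    hom = (called[:, 0] == called[:, 1]).all() and len(np.unique(called)) == 1
    return (int(called[0, 0]) if hom else None), n_missing, False


def classify_locus(
    matrix: GroupedGenotypeMatrix,
    locus_index: int,
    policy: MissingPolicy = MissingPolicy(),
) -> DiagnosticCall:
    """Classify one locus as diagnostic / non_diagnostic / indeterminate.

    Diagnostic requires: per-group missing counts within policy, every
    called group-A sample homozygous for one allele, every called group-B
    sample homozygous for a *different* allele, the focal ALT being one of
    the two fixed alleles, and the two fixed alleles differing in length
    (the contrast must itself be an InDel).
    """
    locus = matrix.loci[locus_index]
    ga_cols = matrix.group_columns(matrix.groups[0])
    gb_cols = matrix.group_columns(matrix.groups[1])
    allele_a, miss_a, indet_a = _group_state(matrix.gt[locus_index, ga_cols], policy.max_missing_per_group)
    allele_b, miss_b, indet_b = _group_state(matrix.gt[locus_index, gb_cols], policy.max_missing_per_group)
    if indet_a or indet_b:
        return DiagnosticCall(locus, STATUS_INDETERMINATE, n_missing_a=miss_a, n_missing_b=miss_b)
    if (
        allele_a is not None
        and allele_b is not None
        and allele_a != allele_b
        and locus.alt_index in (allele_a, allele_b)
        and len(locus.allele(allele_a)) != len(locus.allele(allele_b))
    ):
        return DiagnosticCall(
            locus, STATUS_DIAGNOSTIC,
            group_a_allele=allele_a, group_b_allele=allele_b,
            n_missing_a=miss_a, n_missing_b=miss_b,
        )
    return DiagnosticCall(locus, STATUS_NON_DIAGNOSTIC, n_missing_a=miss_a, n_missing_b=miss_b)


def scan(
    matrix: GroupedGenotypeMatrix, policy: MissingPolicy = MissingPolicy()
) -> list[DiagnosticCall]:
    """All diagnostic calls, sorted by InDel length descending.

    Ties break by (chrom, pos) ascending, so the ordering is total. An
    alt-vs-alt fixed contrast at a multiallelic site would be seen from
    both of its decomposed loci; only the first per (chrom, pos, allele
    pair) is kept.
    """
    calls: list[DiagnosticCall] = []
    seen: set[tuple[str, int, frozenset]] = set()
    for i in range(matrix.n_loci):
        call = classify_locus(matrix, i, policy)
        if call.status != STATUS_DIAGNOSTIC:
            continue
        key = (
            call.locus.chrom,
            call.locus.pos,
            frozenset((call.group_a_allele, call.group_b_allele)),
        )
        if key in seen:
            continue
        seen.add(key)
        calls.append(call)
    calls.sort(key=lambda c: (-c.contrast_length_bp, c.locus.chrom, c.locus.pos))
    return calls


def summarize_samples(matrix: GroupedGenotypeMatrix) -> pd.DataFrame:
    """Per-sample genotype-class counts over all loci.

    Columns: sample, group, n_ref_homo (0/0), n_alt_homo (homozygous for a
    non-reference allele), n_het, n_missing, n_total. The four class
    counts always sum to n_total. Heterozygotes are reported separately so
    either reading of a "total InDels" figure (with or without them) can
    be reconstructed.
    """
    rows = []
    for j, s in enumerate(matrix.samples):
        g = matrix.gt[:, j, :]
        missing = (g == MISSING).any(axis=1)
        hom = (g[:, 0] == g[:, 1]) & ~missing
        n_ref_homo = int((hom & (g[:, 0] == 0)).sum())
        n_alt_homo = int((hom & (g[:, 0] != 0)).sum())
        n_het = int(((g[:, 0] != g[:, 1]) & ~missing).sum())
        rows.append(
            {
                "sample": s,
                "group": matrix.group_of[s],
                "n_ref_homo": n_ref_homo,
                "n_alt_homo": n_alt_homo,
                "n_het": n_het,
                "n_missing": int(missing.sum()),
                "n_total": matrix.n_loci,
            }
        )
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[DiagnosticCall]) -> pd.DataFrame:
    cols = [
        "chrom", "pos", "ref", "alt", "indel_length_bp",
        "a_allele", "b_allele", "status",
    ]
    rows = [
        {
            "chrom": c.locus.chrom,
            "pos": c.locus.pos,
            "ref": c.locus.ref,
            "alt": c.locus.alt,
            "indel_length_bp": c.contrast_length_bp,
            "a_allele": c.group_a_allele,
            "b_allele": c.group_b_allele,
            "status": c.status,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=cols)


def write_calls_tsv(calls: list[DiagnosticCall], path: Path | str) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_calls_vcf(
    matrix: GroupedGenotypeMatrix, calls: list[DiagnosticCall], path: Path | str
) -> None:
    """Diagnostic loci as a filtered VCF (GT-only), in scan order."""
    header = pysam.VariantHeader()
    chrom_order = list(dict.fromkeys(l.chrom for l in matrix.loci))
    for chrom in chrom_order:
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.samples:
        header.add_sample(s)
    index = {(l.chrom, l.pos, l.alt_index): i for i, l in enumerate(matrix.loci)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in calls:
            locus = call.locus
            i = index[(locus.chrom, locus.pos, locus.alt_index)]
            rec = vcf.new_record(
                contig=locus.chrom, start=locus.pos - 1,
                alleles=(locus.ref, *locus.alts),
            )
            for j, s in enumerate(matrix.samples):
                a0, a1 = (int(x) for x in matrix.gt[i, j])
                rec.samples[s]["GT"] = (
                    (None, None) if MISSING in (a0, a1) else (a0, a1)
                )
            vcf.write(rec)


def load_calls_tsv(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "indel_length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df
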