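"""Codominant band-pattern genotyping on a virtual agarose gel.

A diagnostic InDel marker amplifies a different fragment size from each
allele, so on a gel a homozygote shows one band, a heterozygote two —
the property that makes F1 hybrids between two fixed groups directly
observable (both parental fragments amplified simultaneously). This
module predicts band patterns from genotypes, models two practical
failure modes — limited agarose resolvability (bands closer than a
minimum size difference merge) and allelic dropout (each band of a
heterozygote independently lost with some probability, so a heterozygote
can masquerade as a homozygote) — and calls genotype classes back from
band patterns. A marker panel is evaluated by requiring every tested
individual's call to match its pedigree class; markers showing dropout
suspicion or miscalls are rejected, mirroring how a marker whose
heterozygotes sometimes show a single parental band must be discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

CALL_HOM_A = "hom_allele_a"
CALL_HOM_B = "hom_allele_b"
CALL_HET = "heterozygote"
CALL_DROPOUT = "dropout_suspect"
CALL_FAIL = "fail"

CLASS_PARENTAL_A = "parental_a"
CLASS_PARENTAL_B = "parental_b"
CLASS_F1 = "f1"

#: Expected genotype call per pedigree class at a diagnostic marker.
EXPECTED_CALL = {
    CLASS_PARENTAL_A: CALL_HOM_A,
    CLASS_PARENTAL_B: CALL_HOM_B,
    CLASS_F1: CALL_HET,
}


@dataclass(frozen=True)
class MarkerAlleles:
    """Gel-facing view of a marker: the two allele amplicon sizes.

    ``size_a`` is the group-A allele's amplicon, ``size_b`` the group-B
    (reference) allele's.
    """

    marker_id: str
    size_a: int
    size_b: int

    def __post_init__(self) -> None:
        if self.size_a <= 0 or self.size_b <= 0:
            raise DataError(f"{self.marker_id}: amplicon sizes must be positive")
        if self.size_a == self.size_b:
            raise DataError(f"{self.marker_id}: allele amplicons are indistinguishable")

    def size_of(self, allele: str) -> int:
        if allele == "a":
            return self.size_a
        if allele == "b":
            return self.size_b
        raise DataError(f"{self.marker_id}: unknown allele {allele!r}")


@dataclass(frozen=True)
class GelModel:
    """Agarose resolvability: bands closer than ``min_resolvable_diff`` bp
    co-migrate and are reported as a single band. The default 20 bp is a
    practical floor for a 2% gel read by eye."""

    agarose_percent: float = 2.0
    min_resolvable_diff: int = 20

    def __post_init__(self) -> None:
        if self.min_resolvable_diff <= 0:
            raise ConfigurationError("min_resolvable_diff must be > 0")

    def resolvable(self, size1: int, size2: int) -> bool:
        return abs(size1 - size2) >= self.min_resolvable_diff


@dataclass(frozen=True)
class BandPattern:
    marker_id: str
    sample_id: str
    bands: frozenset[int]
    source: str = "predicted"  # predicted | observed

    def __post_init__(self) -> None:
        if len(self.bands) > 2:
            raise DataError(
                f"{self.marker_id}/{self.sample_id}: a biallelic marker yields at most 2 bands"
            )


@dataclass(frozen=True)
class GenotypeCall:
    marker_id: str
    sample_id: str
    call: str
    expected_bands: frozenset[int]
    observed_bands: frozenset[int]
    reason: str = ""


def predict_bands(
    marker: MarkerAlleles,
    genotype: tuple[str, str],
    sample_id: str = "",
    gel: GelModel = GelModel(),
    dropout_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> BandPattern:
    """Predict the band pattern of one diploid genotype at one marker.

    ``genotype`` is a pair over the marker's alleles ``("a", "b")``. A
    homozygote yields its allele's single band. A heterozygote yields both
    bands, but each band is independently lost with probability
    ``dropout_rate``; surviving bands closer than the gel's resolvable
    difference merge into one reported band (midpoint size) with a logged
    warning.
    """
    if not 0.0 <= dropout_rate <= 1.0:
        raise ConfigurationError("dropout_rate must be in [0, 1]")
    sizes = {marker.size_of(a) for a in genotype}
    if len(sizes) == 2 and dropout_rate > 0:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        sizes = {s for s in sizes if rng.random() >= dropout_rate}
    if len(sizes) == 2 and not gel.resolvable(*sorted(sizes)):
        merged = round(sum(sizes) / 2)
        logger.warning(
            "%s/%s: bands %s not resolvable on a %.1f%% gel; reported as one band",
            marker.marker_id, sample_id, sorted(sizes), gel.agarose_percent,
        )
        sizes = {merged}
    return BandPattern(marker.marker_id, sample_id, frozenset(sizes))


def call_genotype(
    marker: MarkerAlleles,
    pattern: BandPattern,
    pedigree_expectation: str | None = None,
    size_tolerance: int = 5,
) -> GenotypeCall:
    """Call a genotype class from a band pattern.

    Bands are matched to the marker's allele sizes within
    ``size_tolerance`` bp. Two distinct matched bands → heterozygote; one
    matched band → homozygote for that allele, unless the pedigree
    expectation is a heterozygote, in which case the single band is
    flagged ``dropout_suspect`` (allelic dropout or a null allele — the
    pattern cannot distinguish the two). No matched band → fail; a band
    within tolerance of both alleles → fail ("unresolvable").
    """
    expected = frozenset({marker.size_a, marker.size_b})
    matched: set[str] = set()
    for band in pattern.bands:
        near_a = abs(band - marker.size_a) <= size_tolerance
        near_b = abs(band - marker.size_b) <= size_tolerance
        if near_a and near_b:
            return GenotypeCall(
                marker.marker_id, pattern.sample_id, CALL_FAIL,
                expected, pattern.bands, reason="unresolvable",
            )
        if near_a:
            matched.add("a")
        elif near_b:
            matched.add("b")
    if len(matched) == 2:
        return GenotypeCall(marker.marker_id, pattern.sample_id, CALL_HET, expected, pattern.bands)
    if len(matched) == 1:
        allele = matched.pop()
        if pedigree_expectation in (CALL_HET, CLASS_F1):
            return GenotypeCall(
                marker.marker_id, pattern.sample_id, CALL_DROPOUT,
                expected, pattern.bands,
                reason=f"single {allele!r} band where pedigree implies a heterozygote",
            )
        return GenotypeCall(
            marker.marker_id, pattern.sample_id,
            CALL_HOM_A if allele == "a" else CALL_HOM_B,
            expected, pattern.bands,
        )
    return GenotypeCall(
        marker.marker_id, pattern.sample_id, CALL_FAIL,
        expected, pattern.bands, reason="no band matched an allele size",
    )


@dataclass
class PanelReport:
    """Per-marker acceptance decisions plus the underlying confusion table."""

    per_marker: pd.DataFrame
    confusion: pd.DataFrame

    @property
    def accepted(self) -> list[str]:
        if self.per_marker.empty:
            return []
        return self.per_marker.loc[self.per_marker["accepted"], "marker_id"].tolist()

    @property
    def rejected(self) -> list[str]:
        if self.per_marker.empty:
            return []
        return self.per_marker.loc[~self.per_marker["accepted"], "marker_id"].tolist()


def evaluate_marker_panel(
    calls: list[GenotypeCall],
    class_of: dict[str, str],
) -> PanelReport:
    """Score a marker panel against pedigree classes.

    ``class_of`` maps each sample to parental_a / parental_b / f1. A
    marker is accepted iff every tested individual's call equals the call
    its class predicts — zero miscalls, zero dropout suspects, zero
    fails. Rejected markers carry the evidence in their reason column.
    With no calls, the report is empty and no acceptance decision is made.
    """
    if not calls:
        empty = pd.DataFrame(
            columns=["marker_id", "n_tested", "n_correct", "n_miscall",
                     "n_dropout_suspect", "n_fail", "accepted", "reasons"]
        )
        conf = pd.DataFrame(columns=["marker_id", "class", "call", "count"])
        return PanelReport(per_marker=empty, confusion=conf)
    unknown = {c.sample_id for c in calls} - set(class_of)
    if unknown:
        raise ConfigurationError(f"samples without a pedigree class: {sorted(unknown)}")
    rows = []
    conf_rows: dict[tuple[str, str, str], int] = {}
    by_marker: dict[str, list[GenotypeCall]] = {}
    for c in calls:
        by_marker.setdefault(c.marker_id, []).append(c)
    for marker_id, mcalls in by_marker.items():
        n_correct = n_miscall = n_dropout = n_fail = 0
        reasons = []
        for c in mcalls:
            cls = class_of[c.sample_id]
            key = (marker_id, cls, c.call)
            conf_rows[key] = conf_rows.get(key, 0) + 1
            if c.call == EXPECTED_CALL[cls]:
                n_correct += 1
            elif c.call == CALL_DROPOUT:
                n_dropout += 1
                reasons.append(f"{c.sample_id}: {c.reason}")
            elif c.call == CALL_FAIL:
                n_fail += 1
                reasons.append(f"{c.sample_id}: fail ({c.reason})")
            else:
                n_miscall += 1
                reasons.append(
                    f"{c.sample_id}: called {c.call}, expected {EXPECTED_CALL[cls]}"
                )
        rows.append(
            {
                "marker_id": marker_id,
                "n_tested": len(mcalls),
                "n_correct": n_correct,
                "n_miscall": n_miscall,
                "n_dropout_suspect": n_dropout,
                "n_fail": n_fail,
                "accepted": n_miscall == 0 and n_dropout == 0 and n_fail == 0,
                "reasons": "; ".join(reasons),
            }
        )
    confusion = pd.DataFrame(
        [
            {"marker_id": m, "class": cls, "call": call, "count": n}
            for (m, cls, call), n in sorted(conf_rows.items())
        ],
        columns=["marker_id", "class", "call", "count"],
    )
    return PanelReport(per_marker=pd.DataFrame(rows), confusion=confusion)


def bands_to_frame(patterns: list[BandPattern]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker_id": p.marker_id,
                "sample_id": p.sample_id,
                "band_sizes": ",".join(str(b) for b in sorted(p.bands)),
                "source": p.source,
            }
            for p in patterns
        ],
        columns=["marker_id", "sample_id", "band_sizes", "source"],
    )


def load_bands_tsv(path) -> list[BandPattern]:
    """Read an observed band table: marker_id, sample_id, band_sizes (comma
    separated bp)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker_id", "sample_id", "band_sizes"}
    if required - set(df.columns):
        raise DataError(f"{path}: band table needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        raw = str(row["band_sizes"]).strip()
        bands = frozenset(
            int(x) for x in raw.split(",") if x and x.lower() not in {"nan", "."}
        )
        out.append(
            BandPattern(row["marker_id"], row["sample_id"], bands, source="observed")
        )
    return out
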