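"""PCR marker design over diagnostic InDel loci.

For each diagnostic locus longer than a minimum InDel length, searches
the reference flanks for a primer pair such that both allele amplicons
fall within the size window and both primers satisfy melting-temperature
and GC bounds. Because the two allele templates differ only by the InDel
between the primer binding sites, the two amplicon sizes always differ
by exactly the InDel length — the property that makes the marker
codominant and gel-scorable.

Defaults mirror a standard agarose-resolvable design: amplicon 150–400
bp, Tm 48–60 °C, GC 40–60 %, InDels > 20 bp, with candidates tiered by
InDel length (> 50, > 40, > 34, > 20 bp).

Melting temperatures use nearest-neighbor thermodynamics with the
unified DNA parameter set of Allawi & SantaLucia (1997) and the
SantaLucia (1998) monovalent-salt entropy correction; the hand-checkable
Wallace rule (2 °C per A/T + 4 °C per G/C) is available as an
alternative method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import IndelLocus
from .errors import ConfigurationError, DataError
from .scan import DiagnosticCall

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Unified nearest-neighbor parameters, Allawi & SantaLucia (1997):
# {stack: (dH kcal/mol, dS cal/(mol*K))}, 5'->3' top strand.
_NN_PARAMS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Duplex-initiation terms for terminal base pairs.
_NN_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
_R_GAS = 1.987  # cal/(mol*K)

TIER_THRESHOLDS = (50, 40, 34, 20)  # bp, descending
TIER_LABELS = (">50", ">40", ">34", ">20")


def _check_sequence(seq: str) -> str:
    if not seq:
        raise DataError("empty primer sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise DataError(f"ambiguous bases in primer sequence: {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC content in percent: 100 * (G + C) / length."""
    seq = _check_sequence(seq)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    seq: str,
    method: str = "nn",
    na_mM: float = 50.0,
    dnac1_nM: float = 25.0,
    dnac2_nM: float = 25.0,
) -> float:
    """Primer melting temperature in degrees Celsius.

    ``method="wallace"``: the Wallace rule 2*(A+T) + 4*(G+C), adequate
    for short oligos and exactly hand-checkable. ``method="nn"``
    (default): two-state nearest-neighbor model,

        Tm = 1000*dH / (dS + dS_salt + R*ln(CT)) - 273.15

    with the unified Allawi & SantaLucia (1997) stack parameters,
    initiation terms for the terminal base pairs, the SantaLucia (1998)
    entropy salt correction dS_salt = 0.368 * (N-1) * ln[Na+], and
    CT = dnac1 - dnac2/2 (non-self-complementary annealing, molar).
    """
    seq = _check_sequence(seq)
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return float(2 * at + 4 * gc)
    if method != "nn":
        raise ConfigurationError(f"unknown Tm method {method!r}")
    if len(seq) < 2:
        raise DataError("nearest-neighbor Tm needs at least 2 bases")
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        h, s = _NN_INIT[term]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN_PARAMS[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    ct = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    return 1000.0 * dh / (ds + _R_GAS * math.log(ct)) - 273.15


@dataclass(frozen=True)
class PrimerConstraints:
    amplicon_min: int = 150
    amplicon_max: int = 400
    tm_min: float = 48.0
    tm_max: float = 60.0
    gc_min: float = 40.0
    gc_max: float = 60.0
    primer_len_range: tuple[int, int] = (18, 27)
    min_indel_length: int = 20  # strict: InDels must be longer than this
    tm_method: str = "nn"
    check_flank_uniqueness: bool = True
    uniqueness_window: int = 10_000  # bp each side of the locus

    def __post_init__(self) -> None:
        if not (0 < self.amplicon_min < self.amplicon_max):
            raise ConfigurationError("need 0 < amplicon_min < amplicon_max")
        if not self.tm_min < self.tm_max:
            raise ConfigurationError("need tm_min < tm_max")
        if not self.gc_min < self.gc_max:
            raise ConfigurationError("need gc_min < gc_max")
        lo, hi = self.primer_len_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("bad primer length range")

    def primer_ok(self, seq: str) -> bool:
        if not self.gc_min <= gc_content(seq) <= self.gc_max:
            return False
        tm = melting_temperature(seq, method=self.tm_method)
        return self.tm_min <= tm <= self.tm_max


def assign_tier(indel_length_bp: int) -> str | None:
    """Length tier; tiers partition (20, inf): >50, (40,50], (34,40], (20,34]."""
    for threshold, label in zip(TIER_THRESHOLDS, TIER_LABELS):
        if indel_length_bp > threshold:
            return label
    return None


@dataclass(frozen=True)
class MarkerCandidate:
    marker_id: str
    locus: IndelLocus
    fwd_seq: str
    fwd_start: int  # 1-based inclusive genomic coords on the reference
    fwd_end: int
    rev_seq: str
    rev_start: int
    rev_end: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    amplicon_bp_allele_ref: int
    amplicon_bp_allele_alt: int
    tier: str

    @property
    def amplicon_diff_bp(self) -> int:
        return abs(self.amplicon_bp_allele_ref - self.amplicon_bp_allele_alt)


@dataclass
class DesignReport:
    candidates: list[MarkerCandidate] = field(default_factory=list)
    skipped: list[tuple[IndelLocus, str]] = field(default_factory=list)


_BASE_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_NN_DH = np.zeros(16)
_NN_DS = np.zeros(16)
for _stack, (_h, _s) in _NN_PARAMS.items():
    _NN_DH[4 * _BASE_CODE[ord(_stack[0])] + _BASE_CODE[ord(_stack[1])]] = _h
    _NN_DS[4 * _BASE_CODE[ord(_stack[0])] + _BASE_CODE[ord(_stack[1])]] = _s
_INIT_DH = np.array([_NN_INIT[b][0] for b in "ACGT"])
_INIT_DS = np.array([_NN_INIT[b][1] for b in "ACGT"])


def _valid_primers(
    seq: str, lo: int, hi: int, constraints: PrimerConstraints, reverse: bool
) -> list[tuple[int, int, str]]:
    """Feasible primers with binding site inside [lo, hi] (1-based, on the
    reference top strand). Returns (start, end, primer 5'->3' sequence).

    Vectorized sliding-window evaluation. The unified NN table is
    reverse-complement symmetric (a duplex and its reverse complement have
    identical dH/dS), so a reverse primer's Tm and GC equal those of its
    top-strand binding site and need no separate pass.
    """
    region = seq[lo - 1 : hi]
    if len(region) < constraints.primer_len_range[0]:
        return []
    codes = _BASE_CODE[np.frombuffer(region.encode(), dtype=np.uint8)]
    valid = codes >= 0
    gc_flag = (codes == 1) | (codes == 2)
    pair_idx = 4 * np.clip(codes[:-1], 0, 3) + np.clip(codes[1:], 0, 3)
    dh_pair = _NN_DH[pair_idx]
    ds_pair = _NN_DS[pair_idx]
    cum_dh = np.concatenate(([0.0], np.cumsum(dh_pair)))
    cum_ds = np.concatenate(([0.0], np.cumsum(ds_pair)))
    cum_gc = np.concatenate(([0], np.cumsum(gc_flag)))
    cum_ok = np.concatenate(([0], np.cumsum(~valid)))
    if constraints.tm_method == "wallace":
        cum_at = np.concatenate(([0], np.cumsum(valid & ~gc_flag)))
    ct_term = _R_GAS * math.log(25e-9 * 0.5)  # dnac1=25, dnac2=25 nM
    salt = 0.368 * math.log(50.0 / 1000.0)
    out: list[tuple[int, int, str]] = []
    pmin, pmax = constraints.primer_len_range
    for plen in range(pmin, pmax + 1):
        n = len(region) - plen + 1
        if n <= 0:
            continue
        starts = np.arange(n)
        ok = (cum_ok[starts + plen] - cum_ok[starts]) == 0
        gc_pct = 100.0 * (cum_gc[starts + plen] - cum_gc[starts]) / plen
        ok &= (gc_pct >= constraints.gc_min) & (gc_pct <= constraints.gc_max)
        if constraints.tm_method == "wallace":
            gc_n = cum_gc[starts + plen] - cum_gc[starts]
            at_n = cum_at[starts + plen] - cum_at[starts]
            tm = 2.0 * at_n + 4.0 * gc_n
        else:
            dh = cum_dh[starts + plen - 1] - cum_dh[starts]
            ds = cum_ds[starts + plen - 1] - cum_ds[starts]
            dh = dh + _INIT_DH[np.clip(codes[starts], 0, 3)] + _INIT_DH[np.clip(codes[starts + plen - 1], 0, 3)]
            ds = ds + _INIT_DS[np.clip(codes[starts], 0, 3)] + _INIT_DS[np.clip(codes[starts + plen - 1], 0, 3)]
            ds = ds + salt * (plen - 1)
            tm = 1000.0 * dh / (ds + ct_term) - 273.15
        ok &= (tm >= constraints.tm_min) & (tm <= constraints.tm_max)
        for s0 in np.nonzero(ok)[0]:
            start = lo + int(s0)
            site = region[s0 : s0 + plen]
            primer = revcomp(site) if reverse else site
            out.append((start, start + plen - 1, primer))
    out.sort()
    return out


def _unique_in_window(seq: str, site: str, center: int, window: int) -> bool:
    lo = max(0, center - window)
    region = seq[lo : center + window]
    return region.count(site) == 1 and region.count(revcomp(site)) == 0


def design_candidates(
    calls: list[DiagnosticCall],
    reference: dict[str, str],
    constraints: PrimerConstraints = PrimerConstraints(),
    marker_prefix: str = "M",
) -> DesignReport:
    """Search primer pairs for each diagnostic locus, longest InDel first.

    Emits at most one candidate per locus: the pair whose reference-allele
    amplicon is closest to the midpoint of the size window (ties: smaller
    amplicon, then leftmost forward primer). Input order — InDel length
    descending from :func:`~indelmark.scan.scan` — is preserved. Loci that
    admit no feasible pair (e.g. too close to a contig edge) are recorded
    in the report with a reason.

    Only reference-vs-alt fixed contrasts are designable: the amplicon on
    the alternate template is the reference amplicon shifted by the
    signed REF/ALT length difference.
    """
    report = DesignReport()
    midpoint = (constraints.amplicon_min + constraints.amplicon_max) / 2.0
    n = 0
    for call in calls:
        locus = call.locus
        length = call.contrast_length_bp
        if length is None or length <= constraints.min_indel_length:
            continue
        if 0 not in (call.group_a_allele, call.group_b_allele):
            report.skipped.append((locus, "alt-vs-alt contrast not designable"))
            continue
        seq = reference.get(locus.chrom)
        if seq is None:
            report.skipped.append((locus, f"chromosome {locus.chrom} not in reference"))
            continue
        cand = _best_pair(locus, seq, constraints, midpoint)
        if cand is None:
            report.skipped.append((locus, "no feasible primer pair"))
            continue
        n += 1
        report.candidates.append(
            MarkerCandidate(
                marker_id=f"{marker_prefix}{n:03d}",
                locus=locus,
                tier=assign_tier(length),
                **cand,
            )
        )
    return report


def _best_pair(
    locus: IndelLocus, seq: str, constraints: PrimerConstraints, midpoint: float
) -> dict | None:
    ref_span_end = locus.pos + len(locus.ref) - 1
    shift = len(locus.alt) - len(locus.ref)  # alt amplicon = ref amplicon + shift
    amax = constraints.amplicon_max
    f_lo = max(1, locus.pos - amax + 1)
    f_hi = locus.pos - 1  # forward primer must end before the variant span
    r_lo = ref_span_end + 1
    r_hi = min(len(seq), ref_span_end + amax - 1)
    if f_hi < f_lo or r_hi < r_lo:
        return None
    pmin = constraints.primer_len_range[0]
    fwd = _valid_primers(seq, f_lo, f_hi, constraints, reverse=False)
    rev = _valid_primers(seq, r_lo, r_hi, constraints, reverse=True)
    if not fwd or not rev:
        return None
    best = _select_pair(locus, seq, constraints, midpoint, shift, fwd, rev)
    if best is None:
        return None
    fs, fe, fseq, rs, re, rseq, amp_ref, amp_alt = best
    return {
        "fwd_seq": fseq, "fwd_start": fs, "fwd_end": fe,
        "rev_seq": rseq, "rev_start": rs, "rev_end": re,
        "tm_f": melting_temperature(fseq, method=constraints.tm_method),
        "tm_r": melting_temperature(rseq, method=constraints.tm_method),
        "gc_f": gc_content(fseq), "gc_r": gc_content(rseq),
        "amplicon_bp_allele_ref": amp_ref, "amplicon_bp_allele_alt": amp_alt,
    }


def _uniqueness_ok(seq, constraints, locus, fs, fe, rs, re) -> bool:
    if not constraints.check_flank_uniqueness:
        return True
    w = constraints.uniqueness_window
    return _unique_in_window(seq, seq[fs - 1 : fe], locus.pos, w) and _unique_in_window(
        seq, seq[rs - 1 : re], locus.pos, w
    )


def _select_pair(locus, seq, constraints, midpoint, shift, fwd, rev):
    """Best feasible pair under the key (|amp_ref - midpoint|, amp_ref,
    fwd start, rev start); ties beyond the key go to the shortest primers.

    The key ignores primer lengths, so only the shortest primer per
    forward start — and per reverse end the one with the smallest start —
    can win; the best reverse end for a given forward start is then found
    by binary search around the ideal amplicon size instead of scanning
    all pairs. Pairs whose primers recur within the flank-uniqueness
    window are rejected; if the winning pair fails that check the search
    falls back to exhaustive key-ordered enumeration.
    """
    # shortest primer per forward start (lists are sorted by (start, end))
    by_fs: dict[int, tuple[int, str]] = {}
    for fs, fe, fseq in fwd:
        if fe < locus.pos and fs not in by_fs:
            by_fs[fs] = (fe, fseq)
    # smallest reverse start (longest primer) per reverse end
    by_re: dict[int, tuple[int, str]] = {}
    for rs, re, rseq in rev:
        if re not in by_re or rs < by_re[re][0]:
            by_re[re] = (rs, rseq)
    if not by_fs or not by_re:
        return None
    re_sorted = sorted(by_re)
    lo_amp = max(constraints.amplicon_min, constraints.amplicon_min - shift)
    hi_amp = min(constraints.amplicon_max, constraints.amplicon_max - shift)
    if lo_amp > hi_amp:
        return None
    import bisect

    best = None
    best_key = None
    for fs in sorted(by_fs):
        lo_re = fs + lo_amp - 1
        hi_re = fs + hi_amp - 1
        ideal = fs + midpoint - 1
        i = bisect.bisect_left(re_sorted, ideal)
        # nearest feasible reverse ends on each side of the ideal size
        for j in (i - 1, i):
            if not 0 <= j < len(re_sorted):
                continue
            re = re_sorted[j]
            if not lo_re <= re <= hi_re:
                # the in-range endpoint nearest the ideal on this side
                re = hi_re if j < i else lo_re
                k = bisect.bisect_right(re_sorted, re) - 1 if j < i else bisect.bisect_left(re_sorted, re)
                if not 0 <= k < len(re_sorted):
                    continue
                re = re_sorted[k]
                if not lo_re <= re <= hi_re:
                    continue
            amp_ref = re - fs + 1
            rs, rseq = by_re[re]
            key = (abs(amp_ref - midpoint), amp_ref, fs, rs)
            if best_key is None or key < best_key:
                best_key = key
                fe, fseq = by_fs[fs]
                best = (fs, fe, fseq, rs, re, rseq, amp_ref, amp_ref + shift)
    if best is None:
        return None
    fs, fe, fseq, rs, re, rseq, amp_ref, amp_alt = best
    if _uniqueness_ok(seq, constraints, locus, fs, fe, rs, re):
        return best
    # rare: winning primers recur nearby; fall back to exhaustive ordering
    pairs = []
    for fs, fe, fseq in fwd:
        if fe >= locus.pos:
            continue
        for rs, re, rseq in rev:
            amp_ref = re - fs + 1
            if lo_amp <= amp_ref <= hi_amp:
                pairs.append(
                    ((abs(amp_ref - midpoint), amp_ref, fs, rs),
                     (fs, fe, fseq, rs, re, rseq, amp_ref, amp_ref + shift))
                )
    pairs.sort(key=lambda p: p[0])
    for _, cand in pairs:
        fs, fe, fseq, rs, re, rseq, amp_ref, amp_alt = cand
        if _uniqueness_ok(seq, constraints, locus, fs, fe, rs, re):
            return cand
    return None


def tier_counts(candidates: list[MarkerCandidate]) -> pd.DataFrame:
    """Candidate counts per mutually exclusive length tier."""
    counts = {label: 0 for label in TIER_LABELS}
    for c in candidates:
        counts[c.tier] += 1
    return pd.DataFrame({"tier": list(TIER_LABELS), "count": [counts[t] for t in TIER_LABELS]})


def candidates_to_frame(candidates: list[MarkerCandidate]) -> pd.DataFrame:
    cols = [
        "marker_id", "chrom", "pos", "ref", "alt", "indel_length_bp",
        "fwd_seq", "fwd_start", "fwd_end", "rev_seq", "rev_start", "rev_end",
        "tm_f", "tm_r", "gc_f", "gc_r",
        "amplicon_bp_allele_ref", "amplicon_bp_allele_alt", "tier",
    ]
    rows = [
        {
            "marker_id": c.marker_id,
            "chrom": c.locus.chrom,
            "pos": c.locus.pos,
            "ref": c.locus.ref,
            "alt": c.locus.alt,
            "indel_length_bp": c.locus.indel_length_bp,
            "fwd_seq": c.fwd_seq, "fwd_start": c.fwd_start, "fwd_end": c.fwd_end,
            "rev_seq": c.rev_seq, "rev_start": c.rev_start, "rev_end": c.rev_end,
            "tm_f": round(c.tm_f, 2), "tm_r": round(c.tm_r, 2),
            "gc_f": round(c.gc_f, 2), "gc_r": round(c.gc_r, 2),
            "amplicon_bp_allele_ref": c.amplicon_bp_allele_ref,
            "amplicon_bp_allele_alt": c.amplicon_bp_allele_alt,
            "tier": c.tier,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=cols)


def write_candidates_tsv(candidates: list[MarkerCandidate], path: Path | str) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def amplicon_templates(
    candidate: MarkerCandidate, reference: dict[str, str]
) -> tuple[str, str]:
    """The (reference-allele, alternate-allele) amplicon sequences."""
    locus = candidate.locus
    seq = reference[locus.chrom]
    ref_amp = seq[candidate.fwd_start - 1 : candidate.rev_end]
    left = seq[candidate.fwd_start - 1 : locus.pos - 1]
    right = seq[locus.pos + len(locus.ref) - 1 : candidate.rev_end]
    alt_amp = left + locus.alt + right
    return ref_amp, alt_amp


def write_amplicon_fasta(
    candidates: list[MarkerCandidate], reference: dict[str, str], path: Path | str
) -> None:
    """Both allele amplicon templates per marker, for sequencing checks."""
    with open(path, "w") as fh:
        for c in candidates:
            ref_amp, alt_amp = amplicon_templates(c, reference)
            fh.write(f">{c.marker_id}_ref {c.locus.chrom}:{c.locus.pos} {len(ref_amp)}bp\n")
            fh.write(ref_amp + "\n")
            fh.write(f">{c.marker_id}_alt {c.locus.chrom}:{c.locus.pos} {len(alt_amp)}bp\n")
            fh.write(alt_amp + "\n")
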