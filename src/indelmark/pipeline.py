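"""End-to-end orchestration: simulate → scan → annotate → design → genotype.

One reproducible run from a single config (YAML-friendly dict), with a
JSON manifest recording each stage's parameters (hashed), inputs,
outputs and headline counts. Identical config + seed reproduces
byte-identical outputs. Any stage failure aborts the run with the stage
name; that stage's partial output directory is renamed with a
``failed_`` prefix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import annotate as ann
from . import design as dsg
from . import genotyping as gtp
from . import scan as scn
from . import simulate as sim
from .errors import ConfigurationError, DataError, IndelmarkError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "scan", "annotate", "design", "genotype")


class StageError(IndelmarkError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    simulate: sim.SimulationConfig | None = None
    # used instead of simulation when provided
    vcf: Path | None = None
    fasta: Path | None = None
    gff: Path | None = None
    groups: Path | None = None
    max_missing: int = 0
    windows: ann.AnnotationWindows = field(default_factory=ann.AnnotationWindows)
    strict: bool = False
    constraints: dsg.PrimerConstraints = field(default_factory=dsg.PrimerConstraints)
    gel: gtp.GelModel = field(default_factory=gtp.GelModel)
    dropout_rate: float = 0.0
    n_f1: int = 8
    n_parent_pairs: int = 4
    size_tolerance: int = 5

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulate is None:
            missing = [n for n in ("vcf", "fasta", "gff", "groups") if getattr(self, n) is None]
            if missing:
                raise ConfigurationError(
                    "either a simulate block or all input paths are required; "
                    f"missing: {missing}"
                )
            for n in ("vcf", "fasta", "gff", "groups"):
                p = Path(getattr(self, n))
                if not p.exists():
                    raise ConfigurationError(f"{n} path does not exist: {p}")


def load_config(path: Path | str) -> PipelineConfig:
    """Build a pipeline config from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    kwargs: dict = {}
    if "outdir" not in raw:
        raise ConfigurationError("config requires an 'outdir'")
    kwargs["outdir"] = Path(raw.pop("outdir"))
    kwargs["seed"] = int(raw.pop("seed", 0))
    if "simulate" in raw:
        s = raw.pop("simulate") or {}
        s.setdefault("seed", kwargs["seed"])
        kwargs["simulate"] = sim.config_from_dict(s)
    for name in ("vcf", "fasta", "gff", "groups"):
        if name in raw:
            kwargs[name] = Path(raw.pop(name))
    if "scan" in raw:
        kwargs["max_missing"] = int((raw.pop("scan") or {}).get("max_missing", 0))
    if "annotate" in raw:
        a = raw.pop("annotate") or {}
        kwargs["strict"] = bool(a.pop("strict", False))
        if a:
            kwargs["windows"] = ann.AnnotationWindows(**a)
    if "design" in raw:
        kwargs["constraints"] = dsg.PrimerConstraints(**(raw.pop("design") or {}))
    if "gel" in raw:
        kwargs["gel"] = gtp.GelModel(**(raw.pop("gel") or {}))
    if "genotype" in raw:
        g = raw.pop("genotype") or {}
        for name in ("dropout_rate", "n_f1", "n_parent_pairs", "size_tolerance"):
            if name in g:
                kwargs[name] = g[name]
    if raw:
        raise ConfigurationError(f"unknown config sections: {sorted(raw)}")
    try:
        return PipelineConfig(**kwargs)
    except TypeError as e:
        raise ConfigurationError(str(e)) from e


def _params_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _read_reference(fasta_path: Path) -> dict[str, str]:
    fa = Fasta(str(fasta_path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def _genotype_letters(gt_row, a_allele: int, b_allele: int) -> tuple[str, str] | None:
    """Map an allele-index genotype onto the marker's two-allele system."""
    letters = []
    for x in gt_row:
        x = int(x)
        if x == a_allele:
            letters.append("a")
        elif x == b_allele:
            letters.append("b")
        else:
            return None
    return tuple(letters)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    state: dict = {}

    def run_stage(name: str, fn, params) -> None:
        stage_dir = out / name
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            info = fn(stage_dir)
        except Exception as e:
            failed = out / f"failed_{name}"
            if failed.exists():  # pragma: no cover - stale reruns
                import shutil

                shutil.rmtree(failed)
            stage_dir.rename(failed)
            raise StageError(name, e) from e
        manifest["stages"].append(
            {
                "stage": name,
                "params_hash": _params_hash(params),
                "outputs": sorted(str(p.relative_to(out)) for p in stage_dir.glob("*")),
                **info,
            }
        )

    # -- simulate ----------------------------------------------------------
    def stage_simulate(stage_dir: Path) -> dict:
        if config.simulate is not None:
            reference, matrix, truth, paths = sim.simulate_dataset(config.simulate, stage_dir)
            state["paths"] = paths
            state["truth"] = truth
            return {"n_loci": matrix.n_loci, "mode": "synthetic"}
        state["paths"] = {
            "vcf": config.vcf, "fasta": config.fasta,
            "gff3": config.gff, "groups": config.groups,
        }
        return {"mode": "provided"}

    run_stage("simulate", stage_simulate, config.simulate)

    # -- scan --------------------------------------------------------------
    def stage_scan(stage_dir: Path) -> dict:
        matrix = scn.load_matrix(state["paths"]["vcf"], state["paths"]["groups"])
        policy = scn.MissingPolicy(max_missing_per_group=config.max_missing)
        calls = scn.scan(matrix, policy)
        scn.write_calls_tsv(calls, stage_dir / "diagnostic_calls.tsv")
        scn.write_calls_vcf(matrix, calls, stage_dir / "diagnostic_calls.vcf")
        scn.summarize_samples(matrix).to_csv(
            stage_dir / "sample_summary.tsv", sep="\t", index=False
        )
        state["matrix"] = matrix
        state["calls"] = calls
        return {"n_loci": matrix.n_loci, "n_diagnostic": len(calls)}

    run_stage("scan", stage_scan, {"max_missing": config.max_missing})

    # -- annotate ----------------------------------------------------------
    def stage_annotate(stage_dir: Path) -> dict:
        gene_models = ann.load_gene_models(state["paths"]["gff3"])
        annotator = ann.Annotator(gene_models, config.windows, strict=config.strict)
        results = annotator.annotate_all(state["matrix"].loci)
        ann.results_to_frame(results).to_csv(
            stage_dir / "annotations.tsv", sep="\t", index=False
        )
        ann.summarize_categories(results).to_csv(
            stage_dir / "category_summary.tsv", sep="\t", index=False
        )
        state["annotations"] = results
        return {"n_annotated": len(results)}

    run_stage("annotate", stage_annotate, dataclasses.asdict(config.windows))

    # -- design ------------------------------------------------------------
    def stage_design(stage_dir: Path) -> dict:
        reference = _read_reference(Path(state["paths"]["fasta"]))
        report = dsg.design_candidates(state["calls"], reference, config.constraints)
        dsg.write_candidates_tsv(report.candidates, stage_dir / "marker_candidates.tsv")
        dsg.write_amplicon_fasta(report.candidates, reference, stage_dir / "amplicons.fa")
        dsg.tier_counts(report.candidates).to_csv(
            stage_dir / "tier_counts.tsv", sep="\t", index=False
        )
        with open(stage_dir / "skipped.tsv", "w") as fh:
            fh.write("chrom\tpos\treason\n")
            for locus, reason in report.skipped:
                fh.write(f"{locus.chrom}\t{locus.pos}\t{reason}\n")
        state["design"] = report
        return {"n_candidates": len(report.candidates), "n_skipped": len(report.skipped)}

    run_stage("design", stage_design, dataclasses.asdict(config.constraints))

    # -- genotype ----------------------------------------------------------
    def stage_genotype(stage_dir: Path) -> dict:
        result = genotype_panel(
            matrix=state["matrix"],
            calls=state["calls"],
            candidates=state["design"].candidates,
            gel=config.gel,
            dropout_rate=config.dropout_rate,
            n_f1=config.n_f1,
            n_parent_pairs=config.n_parent_pairs,
            size_tolerance=config.size_tolerance,
            seed=config.seed,
        )
        gtp.bands_to_frame(result["patterns"]).to_csv(
            stage_dir / "band_patterns.tsv", sep="\t", index=False
        )
        report: gtp.PanelReport = result["report"]
        report.per_marker.to_csv(stage_dir / "panel_report.tsv", sep="\t", index=False)
        report.confusion.to_csv(stage_dir / "panel_confusion.tsv", sep="\t", index=False)
        state["panel"] = report
        return {
            "n_markers_tested": int(report.per_marker.shape[0]),
            "n_accepted": len(report.accepted),
        }

    run_stage(
        "genotype",
        stage_genotype,
        {
            "dropout_rate": config.dropout_rate,
            "n_f1": config.n_f1,
            "size_tolerance": config.size_tolerance,
            **dataclasses.asdict(config.gel),
        },
    )

    manifest["funnel"] = {
        "loci": manifest["stages"][1]["n_loci"],
        "diagnostic": manifest["stages"][1]["n_diagnostic"],
        "designed": manifest["stages"][3]["n_candidates"],
        "accepted": manifest["stages"][4]["n_accepted"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    state["manifest"] = manifest
    run_pipeline.last_state = state  # inspection hook for library callers
    return manifest


def genotype_panel(
    matrix,
    calls,
    candidates,
    gel: gtp.GelModel = gtp.GelModel(),
    dropout_rate: float = 0.0,
    n_f1: int = 8,
    n_parent_pairs: int = 4,
    size_tolerance: int = 5,
    seed: int = 0,
) -> dict:
    """Simulate an F1 validation panel over designed markers.

    Crosses ``n_parent_pairs`` (group-A x group-B) parent pairs to produce
    ``n_f1`` offspring, predicts band patterns for every parent and F1 at
    every marker (with per-band dropout in heterozygotes), calls genotypes
    against pedigree expectations and evaluates marker acceptance.
    """
    rng = np.random.default_rng([seed, 1000])
    call_by_pos = {(c.locus.chrom, c.locus.pos): c for c in calls}
    locus_index = {(l.chrom, l.pos, l.alt_index): i for i, l in enumerate(matrix.loci)}

    a_samples = [s for s in matrix.samples if matrix.group_of[s] == matrix.groups[0]]
    b_samples = [s for s in matrix.samples if matrix.group_of[s] == matrix.groups[1]]
    n_pairs = min(n_parent_pairs, len(a_samples), len(b_samples))
    pairs = [(a_samples[i], b_samples[i]) for i in range(n_pairs)]

    # F1 genotypes across all matrix loci, offspring assigned to pairs round-robin
    f1_gt: dict[str, np.ndarray] = {}
    class_of: dict[str, str] = {}
    for s in a_samples:
        class_of[s] = gtp.CLASS_PARENTAL_A
    for s in b_samples:
        class_of[s] = gtp.CLASS_PARENTAL_B
    col = {s: j for j, s in enumerate(matrix.samples)}
    for k in range(n_f1 if pairs else 0):
        pa, pb = pairs[k % len(pairs)]
        child = f"F1_{k + 1:02d}"
        f1_gt[child] = sim.simulate_f1(
            (matrix.loci, matrix.gt[:, col[pa], :]),
            (matrix.loci, matrix.gt[:, col[pb], :]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        class_of[child] = gtp.CLASS_F1

    patterns: list[gtp.BandPattern] = []
    genotype_calls: list[gtp.GenotypeCall] = []
    for cand in candidates:
        key = (cand.locus.chrom, cand.locus.pos)
        dcall = call_by_pos.get(key)
        if dcall is None:
            raise DataError(f"candidate {cand.marker_id} has no diagnostic call")
        # amplicon size of each group's allele (reference carries allele 0)
        size_of_index = {
            0: cand.amplicon_bp_allele_ref,
            cand.locus.alt_index: cand.amplicon_bp_allele_alt,
        }
        marker = gtp.MarkerAlleles(
            marker_id=cand.marker_id,
            size_a=size_of_index[dcall.group_a_allele],
            size_b=size_of_index[dcall.group_b_allele],
        )
        li = locus_index[(cand.locus.chrom, cand.locus.pos, cand.locus.alt_index)]
        individuals = [(s, matrix.gt[li, col[s], :]) for s in a_samples + b_samples]
        individuals += [(s, f1_gt[s][li]) for s in sorted(f1_gt)]
        for sample_id, gt_row in individuals:
            letters = _genotype_letters(gt_row, dcall.group_a_allele, dcall.group_b_allele)
            if letters is None:
                continue  # missing or off-system allele: no lane for this sample
            pattern = gtp.predict_bands(
                marker, letters, sample_id=sample_id, gel=gel,
                dropout_rate=dropout_rate, rng=rng,
            )
            patterns.append(pattern)
            genotype_calls.append(
                gtp.call_genotype(
                    marker, pattern,
                    pedigree_expectation=class_of[sample_id],
                    size_tolerance=size_tolerance,
                )
            )
    report = gtp.evaluate_marker_panel(genotype_calls, class_of)
    return {"patterns": patterns, "calls": genotype_calls, "report": report,
            "class_of": class_of}


def report(manifest: dict | Path | str) -> str:
    """Human-readable end-to-end summary from a run manifest."""
    if not isinstance(manifest, dict):
        path = Path(manifest)
        if path.is_dir():
            path = path / "manifest.json"
        with open(path) as fh:
            manifest = json.load(fh)
    lines = ["indelmark pipeline report", "=" * 25]
    done = {s["stage"] for s in manifest.get("stages", [])}
    missing = [s for s in STAGES if s not in done]
    if missing:
        lines.append(f"PARTIAL RUN — missing stages: {', '.join(missing)}")
    lines.append(f"seed: {manifest.get('seed')}")
    funnel = manifest.get("funnel")
    if funnel:
        lines.append("")
        lines.append("funnel (loci -> diagnostic -> designed -> accepted):")
        lines.append(
            "  {loci} -> {diagnostic} -> {designed} -> {accepted}".format(**funnel)
        )
    for s in manifest.get("stages", []):
        extras = {
            k: v for k, v in s.items() if k not in {"stage", "params_hash", "outputs"}
        }
        lines.append("")
        lines.append(f"[{s['stage']}] params {s['params_hash']}")
        for k, v in extras.items():
            lines.append(f"  {k}: {v}")
        for o in s.get("outputs", []):
            lines.append(f"  out: {o}")
    return "\n".join(lines) + "\n"
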