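"""Configuration-driven orchestration of the full workflow.

Stages (simulate → qc → align → subtract → damage → tracer → stats)
each read their inputs from, and persist their outputs to, a fixed
layout under the run directory, so any stage can be re-run from its
predecessor's files. A run manifest snapshots the configuration, input
checksums and the stage-by-stage read-count chain.
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

from . import __version__
from .align import (
    Assignment,
    TaxonProfile,
    align_batch,
    build_profile,
    hits_to_tsv,
    project_rank,
)
from .damage import (
    calls_to_tsv,
    classify_read,
    damage_proportion,
    fit_decay,
    substitution_spectrum,
)
from .qc import Read, read_fastq, run_qc, write_fastq
from .stats import correlations_to_tsv, group_rare, pearson_matrix, relative_abundance
from .subtract import subtract_controls
from .synthetic import default_config, simulate_core
from .taxonomy import load_references, load_taxonomy, merge_databases, write_references, write_taxonomy
from .tracer import assess_contamination, blank_correct, runs_from_tsv, verdicts_to_tsv

logger = logging.getLogger("sedadna")

STAGES = ("simulate", "qc", "align", "subtract", "damage", "tracer", "stats")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """All stage parameters in one auditable document."""

    seed: int = 0
    outdir: str = "run"
    simulate: bool = True
    reads_per_sample: int = 5000
    # read QC
    min_len: int = 25
    complexity_threshold: float = 0.55
    complexity_k: int = 4
    # alignment / assignment
    min_pid: float = 0.95
    top_percent: float = 0.10
    min_seed: int = 1
    min_support_percent: float = 0.0
    rank: str = "phylum"
    # control subtraction
    subtraction_mode: str = "remove_taxon"
    subtraction_scope: str = "per_site"
    # damage
    k_terminal: int = 5
    min_reads: int = 50
    # rarefaction: null = off, "auto" = smallest marker-bearing library
    rarefaction_depth: int | str | None = None
    # tracer
    tracer_ddof: int = 1

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError("config", "unknown_keys", str(sorted(unknown)))
        return cls(**data)


@dataclass(frozen=True)
class Finding:
    level: str  # error | warning
    field: str
    message: str


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Range-check every parameter without side effects."""
    findings = []

    def err(field_, msg):
        findings.append(Finding("error", field_, msg))

    def warn(field_, msg):
        findings.append(Finding("warning", field_, msg))

    if config.min_len < 1:
        err("min_len", "must be >= 1")
    if not 0.0 <= config.complexity_threshold <= 1.0:
        err("complexity_threshold", "must be in [0, 1]")
    if config.complexity_k < 1:
        err("complexity_k", "must be >= 1")
    if not 0.0 <= config.min_pid <= 1.0:
        err("min_pid", "must be in [0, 1]")
    if not 0.0 <= config.top_percent <= 1.0:
        err("top_percent", "must be in [0, 1]")
    if not 0.0 <= config.min_support_percent <= 100.0:
        err("min_support_percent", "percent in [0, 100]")
    if config.subtraction_mode not in ("remove_taxon", "subtract_counts"):
        err("subtraction_mode", "remove_taxon or subtract_counts")
    if config.subtraction_scope not in ("per_site", "global"):
        err("subtraction_scope", "per_site or global")
    if config.k_terminal < 1:
        err("k_terminal", "must be >= 1")
    if config.min_reads < 1:
        err("min_reads", "must be >= 1")
    if config.tracer_ddof not in (0, 1):
        err("tracer_ddof", "0 (population SD) or 1 (sample SD)")
    if isinstance(config.rarefaction_depth, int) and config.rarefaction_depth <= 0:
        err("rarefaction_depth", "must be positive, 'auto', or null")
    if (
        isinstance(config.rarefaction_depth, int)
        and config.rarefaction_depth > config.reads_per_sample
    ):
        warn("rarefaction_depth", "exceeds every configured library size")
    if config.reads_per_sample < 1:
        err("reads_per_sample", "must be >= 1")
    return findings


# ---------------------------------------------------------------------------
# Stage implementations (disk-to-disk; restartable)
# ---------------------------------------------------------------------------


def _dir(outdir: str | Path, stage: str) -> Path:
    d = Path(outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(config: PipelineConfig) -> dict:
    d = _dir(config.outdir, "simulate")
    sim = simulate_core(default_config(config.seed, config.reads_per_sample))
    sim.write(d)
    write_taxonomy(sim.tree, d / "taxonomy.tsv")
    for marker, db in sim.dbs.items():
        write_references(db, d / f"refs_{marker}.fasta")
    n = sum(len(v) for v in sim.reads.values())
    logger.info("simulate: %d reads in %d libraries", n, len(sim.reads))
    return {"reads": n, "libraries": len(sim.reads)}


def _load_metadata(outdir) -> pd.DataFrame:
    path = Path(outdir) / "simulate" / "truth_samples.tsv"
    if not path.exists():
        raise PipelineError("qc", "missing_input", f"{path} not found")
    return pd.read_csv(path, sep="\t").set_index("sample_id")


def stage_qc(config: PipelineConfig) -> dict:
    src = Path(config.outdir) / "simulate"
    d = _dir(config.outdir, "qc")
    reads: list[Read] = []
    for fastq in sorted(src.glob("*.fastq")):
        reads.extend(read_fastq(fastq, fastq.stem))
    retained, report = run_qc(
        reads,
        min_len=config.min_len,
        threshold=config.complexity_threshold,
        k=config.complexity_k,
    )
    report.to_tsv(d / "qc_report.tsv")
    by_sample: dict[str, list[Read]] = {}
    for r in retained:
        by_sample.setdefault(r.sample_id, []).append(r)
    for sample_id in sorted({r.sample_id for r in reads}):
        write_fastq(by_sample.get(sample_id, []), d / f"{sample_id}.fastq")
    logger.info("qc: %d of %d reads retained", len(retained), len(reads))
    return {"input": len(reads), "retained": len(retained)}


def _load_db(config: PipelineConfig):
    src = Path(config.outdir) / "simulate"
    tree = load_taxonomy(src / "taxonomy.tsv")
    dbs = []
    for fasta in sorted(src.glob("refs_*.fasta")):
        db, _ = load_references(fasta, tree)
        dbs.append(db)
    if not dbs:
        raise PipelineError("align", "missing_input", "no reference FASTA found")
    return tree, merge_databases(dbs)


def stage_align(config: PipelineConfig) -> dict:
    qc_dir = Path(config.outdir) / "qc"
    d = _dir(config.outdir, "align")
    tree, db = _load_db(config)
    reads = []
    for fastq in sorted(qc_dir.glob("*.fastq")):
        reads.extend(read_fastq(fastq, fastq.stem))
    assignments, best_hits = align_batch(
        reads,
        db,
        tree,
        min_pid=config.min_pid,
        top_percent=config.top_percent,
        min_seed=config.min_seed,
    )
    n_reads = len(reads)
    n_with_hits = len(best_hits)
    profile = build_profile(assignments, tree, config.min_support_percent)
    profile.to_tsv(d / "profile.tsv")
    hits_to_tsv(best_hits, d / "best_hits.tsv")
    pd.DataFrame(assignments).to_csv(d / "assignments.tsv", sep="\t", index=False)
    n_assigned = int(profile.totals().sum())
    logger.info(
        "align: %d reads, %d with hits, %d assigned", n_reads, n_with_hits, n_assigned
    )
    return {"input": n_reads, "with_hits": n_with_hits, "assigned": n_assigned}


def stage_subtract(config: PipelineConfig) -> dict:
    d = _dir(config.outdir, "subtract")
    meta = _load_metadata(config.outdir)
    profile = TaxonProfile.from_tsv(Path(config.outdir) / "align" / "profile.tsv")
    control_ids = [
        s for s in profile.samples if meta.loc[s, "kind"].startswith("control")
    ]
    sample_ids = [s for s in profile.samples if s not in control_ids]
    samples = TaxonProfile(profile.counts.loc[sample_ids], profile.unassigned[sample_ids])
    controls = TaxonProfile(
        profile.counts.loc[control_ids], profile.unassigned[control_ids]
    )
    filtered, report = subtract_controls(
        samples,
        controls,
        mode=config.subtraction_mode,
        scope=config.subtraction_scope,
        sites=meta["site"].to_dict(),
    )
    filtered.to_tsv(d / "profile.tsv")
    report.to_tsv(d / "subtraction_report.tsv")
    report.contaminants_to_tsv(d / "contaminant_taxa.tsv")
    removed = int(report.changes["count_removed"].sum())
    logger.info("subtract: %d reads removed as control-supported", removed)
    return {
        "input": int(samples.totals().sum()),
        "removed": removed,
        "retained": int(filtered.totals().sum()),
    }


def stage_damage(config: PipelineConfig) -> dict:
    d = _dir(config.outdir, "damage")
    meta = _load_metadata(config.outdir)
    with open(Path(config.outdir) / "align" / "best_hits.tsv.json") as fh:
        sidecar = json.load(fh)
    # Reconstruct best hits with their mismatch records.
    from .align import AlignmentHit

    blast = pd.read_csv(
        Path(config.outdir) / "align" / "best_hits.tsv",
        sep="\t",
        header=None,
        names=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )
    seqs: dict[str, str] = {}
    sample_of: dict[str, str] = {}
    for fastq in sorted((Path(config.outdir) / "qc").glob("*.fastq")):
        for read in read_fastq(fastq, fastq.stem):
            seqs[read.read_id] = read.sequence
            sample_of[read.read_id] = read.sample_id
    hits = []
    for row, extra in zip(blast.itertuples(index=False), sidecar):
        mismatches = tuple((int(p), rb, qb) for p, rb, qb in extra["mismatches"])
        gaps = int(row.gapopen)
        columns = int(row.length)
        hits.append(
            AlignmentHit(
                read_id=row.qseqid,
                ref_id=row.sseqid,
                taxon_id=int(extra["taxon_id"]),
                strand=extra["strand"],
                score=int(row.bitscore),
                columns=columns,
                matches=columns - len(mismatches) - gaps,
                mismatches=mismatches,
                gaps=gaps,
                read_insertions=tuple(extra["read_insertions"]),
                ref_start=int(row.sstart) - 1,
                ref_end=int(row.send),
            )
        )
    core_hits = [
        h for h in hits if meta.loc[sample_of[h.read_id], "kind"] == "sample"
    ]
    calls = [
        classify_read(
            h,
            sample_of[h.read_id],
            k_terminal=config.k_terminal,
            min_pid=config.min_pid,
        )
        for h in core_hits
    ]
    summary = damage_proportion(calls, min_reads=config.min_reads)
    calls_to_tsv(calls, d / "read_calls.tsv")
    summary.to_tsv(d / "damage_summary.tsv")
    spectrum = substitution_spectrum(core_hits, seqs)
    spectrum.to_tsv(d / "spectrum.tsv")
    per_sample = summary.per_sample()
    table = meta.loc[meta["kind"] == "sample", ["depth_mbsf", "age_ka"]].copy()
    table["damage_proportion"] = per_sample
    table.to_csv(d / "damage_vs_depth.tsv", sep="\t")
    try:
        fit = fit_decay(spectrum)
        fit_payload = {
            "d_hat": fit.d_hat,
            "r_hat": None if np.isnan(fit.r_hat) else fit.r_hat,
            "eps_hat": fit.eps_hat,
            "rss": fit.rss,
            "degenerate": fit.degenerate,
        }
    except ValueError as exc:
        fit_payload = {"error": str(exc)}
    with open(d / "decay_fit.json", "w") as fh:
        json.dump(fit_payload, fh, indent=1)
    n_ancient = sum(c.call == "ancient" for c in calls)
    logger.info("damage: %d calls, %d ancient", len(calls), n_ancient)
    return {"input": len(calls), "ancient": n_ancient}


def stage_tracer(config: PipelineConfig) -> dict:
    d = _dir(config.outdir, "tracer")
    runs = runs_from_tsv(Path(config.outdir) / "simulate" / "tracer.tsv")
    all_verdicts = []
    summaries = {}
    for run in runs:
        verdicts, summary = assess_contamination(
            blank_correct(run), ddof=config.tracer_ddof
        )
        all_verdicts.extend(verdicts)
        summaries[run.run_id] = summary
    verdicts_to_tsv(all_verdicts, d / "verdicts.tsv")
    with open(d / "summary.json", "w") as fh:
        json.dump(summaries, fh, indent=1, sort_keys=True)
    logger.info("tracer: %d samples assessed over %d runs", len(all_verdicts), len(runs))
    return {"runs": len(runs), "samples": len(all_verdicts)}


def stage_stats(config: PipelineConfig) -> dict:
    d = _dir(config.outdir, "stats")
    meta = _load_metadata(config.outdir)
    src = Path(config.outdir) / "simulate"
    tree = load_taxonomy(src / "taxonomy.tsv")
    profile = TaxonProfile.from_tsv(Path(config.outdir) / "subtract" / "profile.tsv")
    phylum = project_rank(profile, tree, config.rank)
    phylum.to_tsv(d / f"profile_{config.rank}.tsv", tree)
    rel, empty = relative_abundance(phylum)
    # Mudline libraries and empty samples are excluded from statistics.
    mudline = [s for s in rel.index if meta.loc[s, "kind"] == "mudline"]
    rel = rel.drop(index=mudline)
    labelled = rel.copy()
    labelled.columns = [phylum.column_label(t, tree) for t in labelled.columns]
    labelled.to_csv(d / f"relative_abundance_{config.rank}.tsv", sep="\t")
    group_rare(labelled).to_csv(d / "relative_abundance_grouped.tsv", sep="\t")

    # Diatom transition table: fraction vs age.
    diatom_cols = [
        t for t in rel.columns if tree.name(t) == "Bacillariophyta"
    ]
    transition = meta.loc[rel.index, ["age_ka", "depth_mbsf"]].copy()
    transition["diatom_fraction"] = (
        rel[diatom_cols].sum(axis=1) if diatom_cols else 0.0
    )
    transition.to_csv(d / "diatom_transition.tsv", sep="\t")

    # Damage vs geochemistry correlations.
    damage_path = Path(config.outdir) / "damage" / "damage_vs_depth.tsv"
    geochem_path = src / "geochem.tsv"
    n_pairs = 0
    if damage_path.exists() and geochem_path.exists():
        dmg = pd.read_csv(damage_path, sep="\t", index_col=0)
        geo = pd.read_csv(geochem_path, sep="\t", index_col=0)
        keep = [s for s in dmg.index if s not in empty and s not in mudline]
        x = dmg.loc[keep, ["damage_proportion"]]
        y = geo.reindex(keep).drop(columns=["depth_mbsf", "age_ka"], errors="ignore")
        results = pearson_matrix(x, y)
        correlations_to_tsv(results, d / "damage_geochem_correlations.tsv")
        n_pairs = len(results)
    logger.info("stats: %d correlation pairs, %d empty samples", n_pairs, len(empty))
    return {"samples": int(len(rel)), "empty_samples": len(empty), "pairs": n_pairs}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "align": stage_align,
    "subtract": stage_subtract,
    "damage": stage_damage,
    "tracer": stage_tracer,
    "stats": stage_stats,
}


def run_stage(name: str, config: PipelineConfig) -> dict:
    if name not in _STAGE_FUNCS:
        raise PipelineError(name, "unknown_stage", f"no stage named {name}")
    try:
        return _STAGE_FUNCS[name](config)
    except PipelineError:
        raise
    except Exception as exc:  # surface the failing stage
        marker = Path(config.outdir) / f"{name}.failed"
        marker.write_text(str(exc))
        raise PipelineError(name, type(exc).__name__, str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the manifest and run report."""
    findings = validate_config(config)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise PipelineError(
            "config", "invalid", "; ".join(f"{f.field}: {f.message}" for f in errors)
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    try:
        counts = {}
        for stage in STAGES:
            counts[stage] = run_stage(stage, config)
        checksums = {
            p.name: _md5(p) for p in sorted((outdir / "simulate").glob("*.fastq"))
        }
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "input_checksums": checksums,
            "stage_counts": counts,
            "warnings": [dataclasses.asdict(f) for f in findings],
        }
        _validate_chain(counts)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        _write_report(config, counts, outdir)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _validate_chain(counts: dict) -> None:
    if counts["qc"]["input"] != counts["simulate"]["reads"]:
        raise PipelineError("manifest", "count_chain", "simulate → qc mismatch")
    if counts["align"]["input"] != counts["qc"]["retained"]:
        raise PipelineError("manifest", "count_chain", "qc → align mismatch")


def _write_report(config: PipelineConfig, counts: dict, outdir: Path) -> None:
    lines = [
        f"sedadna {__version__} run report (seed {config.seed})",
        "",
        "stage counts:",
    ]
    for stage, c in counts.items():
        lines.append(f"  {stage}: " + ", ".join(f"{k}={v}" for k, v in c.items()))
    dmg = outdir / "damage" / "damage_vs_depth.tsv"
    if dmg.exists():
        lines += ["", "damage vs depth:", dmg.read_text().rstrip()]
    tra = outdir / "tracer" / "summary.json"
    if tra.exists():
        lines += ["", "tracer summary: " + tra.read_text().strip()]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
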