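"""Configuration-driven orchestration of the full analysis.

Runs simulate-or-load -> filter -> merge -> annotate -> RNA maps ->
classify -> intersect -> splice-site / architecture statistics ->
enrichment, writing every output as a TSV plus a manifest recording
parameters, seed and the sha256 of each file.  Identical config + seed
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import io_formats as io
from . import peaks as pk
from . import rna_map, splice, synthetic
from .models import ALTERNATIVE
from .synthetic import SimulationConfig

logger = logging.getLogger("clipmap.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the conventional values for
    this analysis:
    p <= 1e-3 and >= 5-fold for high-confidence peaks, 2-of-4 consensus
    support, 100 nt exon / 300 nt intron metagene windows, 300 nt
    constitutive-exon flanks, |dPSI| > 0.1 with FDR < 0.05, and 1000
    permutations for complex enrichment."""

    output_dir: str = "clipmap_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)
    # peak filtering / merging
    p_threshold: float = 1e-3
    fold_threshold: float = 5.0
    fold_strict: bool = False
    min_support: int = 2
    # RNA maps
    exon_window: int = 100
    intron_window: int = 300
    epsilon: float = 1.0
    n_bins: int = 100
    bin_mode: str = "fractional"
    min_depth: int = 3
    # splice statistics
    dpsi_threshold: float = 0.1
    fdr_threshold: float = 0.05
    flank_nt: int = 300
    # enrichment
    min_term_size: int = 5
    n_perm: int = 1000
    complex_p_cutoff: float = enr.DEFAULT_COMPLEX_P_CUTOFF

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            if "exons_per_gene" in sim:
                sim = {k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and return the output manifest.

    With no explicit inputs the synthetic generator (seeded from
    ``config.seed``) produces annotation, peaks, coverage, events, GO and
    complex inputs; these are written to disk and read back through the
    format readers, so the run exercises the full file contract.  Stages
    whose inputs are absent are skipped with a notice.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("clipmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))

    files: list[Path] = []
    stage_notes: dict[str, str] = {}

    def record(path: Path) -> Path:
        files.append(path)
        return path

    def stage(name: str):
        logger.info("stage %s", name)

    try:
        models, genome, chrom_sizes = _stage_annotation(config, out, record, stage)
        peak_libs = _stage_peaks(config, models, out, record, stage)
        merged = None
        if peak_libs:
            merged = _stage_merge_annotate(config, models, peak_libs, out, record, stage)
        events = planted = None
        if config.simulation is not None or "events" in config.inputs:
            events, planted = _stage_events(config, models, out, record, stage)
        if merged is not None and models:
            _stage_rna_maps(config, models, merged, events, out, record, stage, stage_notes, chrom_sizes)
        else:
            stage_notes["rna_map"] = "skipped: no merged peaks or annotation"
        if events is not None:
            _stage_splice_stats(config, models, genome, merged, events, planted, out, record, stage, stage_notes)
        else:
            stage_notes["splice_stats"] = "skipped: no splicing events provided"
            logger.info("splice stages skipped: no events input")
        _stage_enrichment(config, models, out, record, stage, stage_notes)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(getattr(exc, "_clipmap_stage", "unknown"), exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        "seed": config.seed,
        "parameters": _config_dict(config),
        "notes": stage_notes,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(files))
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("simulation") is not None:
        d["simulation"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d["simulation"].items()}
    return d


def _wrap(stage_name):
    def deco(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(stage_name, exc) from exc
        return inner
    return deco


@_wrap("annotation")
def _stage_annotation(config, out, record, stage):
    stage("annotation")
    if "gtf" in config.inputs:
        models = io.read_gtf(config.inputs["gtf"])
        genome = io.read_fasta(config.inputs["fasta"]) if "fasta" in config.inputs else {}
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        config.simulation = sim
        models, genome = synthetic.simulate_annotation(sim)
        io.write_gtf(models, record(out / "annotation.gtf"))
        io.write_fasta(genome, record(out / "genome.fa"))
        # read back through the format layer so the file contract is exercised
        alt = {
            m.transcript_id: {i for i, lab in enumerate(m.exon_labels) if lab == ALTERNATIVE}
            for m in models
        }
        models = io.read_gtf(out / "annotation.gtf", alt_exon_labels=alt)
    chrom_sizes = synthetic.chrom_sizes_of(genome) if genome else None
    logger.info("annotation: %d transcripts", len(models))
    return models, genome, chrom_sizes


@_wrap("peaks")
def _stage_peaks(config, models, out, record, stage):
    stage("peaks")
    if "peaks" in config.inputs:
        return {lib: io.read_peaks(path, lib) for lib, path in config.inputs["peaks"].items()}
    if config.simulation is None:
        logger.info("peaks skipped: no peak input")
        return {}
    libs = synthetic.simulate_peaks(models, config.simulation)
    loaded = {}
    for lib, peaks in sorted(libs.items()):
        path = record(out / f"peaks_{lib}.bed")
        io.write_peaks(peaks, path)
        loaded[lib] = io.read_peaks(path, lib)
    return loaded


@_wrap("merge_annotate")
def _stage_merge_annotate(config, models, peak_libs, out, record, stage):
    stage("filter+merge+annotate")
    filtered = [
        pk.filter_high_confidence(
            peaks, config.p_threshold, config.fold_threshold, config.fold_strict
        )
        for _, peaks in sorted(peak_libs.items())
    ]
    merged = pk.merge_replicate_peaks(filtered, min_support=config.min_support)
    logger.info(
        "peaks: %s raw -> %s high-confidence -> %d merged",
        sum(len(v) for v in peak_libs.values()), sum(len(v) for v in filtered), len(merged),
    )
    io.write_table(
        (
            {
                "chrom": m.interval.chrom, "start": m.interval.start,
                "end": m.interval.end, "strand": m.interval.strand,
                "support": m.support, "n_sources": len(m.source_ids),
            }
            for m in merged
        ),
        record(out / "merged_peaks.tsv"),
    )
    annotations = pk.annotate_peaks(merged, models)
    io.write_table(pk.annotation_summary(annotations), record(out / "peak_annotation_summary.tsv"))
    return merged


@_wrap("events")
def _stage_events(config, models, out, record, stage):
    stage("events")
    if "events" in config.inputs:
        spec = config.inputs["events"]
        path, dialect = (spec, "simple") if isinstance(spec, str) else (spec["path"], spec.get("dialect", "simple"))
        return io.read_splice_events(path, dialect), None
    events, planted = synthetic.simulate_events(models, config.simulation)
    path = record(out / "splice_events.tsv")
    io.write_splice_events(events, path)
    events = io.read_splice_events(path, "simple")
    io.write_table(
        ({"event_id": e, "planted_class": c} for e, c in sorted(planted.items())),
        record(out / "planted_classes.tsv"),
    )
    return events, planted


@_wrap("rna_map")
def _stage_rna_maps(config, models, merged, events, out, record, stage, notes, chrom_sizes):
    stage("rna_map")
    sim = config.simulation
    if sim is None:
        if not {"coverage_ip", "coverage_input"} <= set(config.inputs):
            notes["rna_map_density"] = "skipped: no coverage input"
            return
        ip = io.read_coverage(*config.inputs["coverage_ip"], chrom_sizes=config.inputs["chrom_sizes"])
        inp = io.read_coverage(*config.inputs["coverage_input"], chrom_sizes=config.inputs["chrom_sizes"])
        ip2 = None
    else:
        ip, inp = synthetic.simulate_coverage(models, merged, sim, chrom_sizes)
        ip2, _ = synthetic.simulate_coverage(models, merged, sim, chrom_sizes, stream=1)
        io.write_coverage(ip, record(out / "coverage_ip_plus.bedgraph"), record(out / "coverage_ip_minus.bedgraph"))
        io.write_coverage(inp, record(out / "coverage_input_plus.bedgraph"), record(out / "coverage_input_minus.bedgraph"))

    boundaries = rna_map.select_boundaries(merged, models)
    logger.info("rna_map: %d boundaries selected", len(boundaries))
    p5, p3 = rna_map.boundary_density(
        boundaries, ip, inp,
        exon_window=config.exon_window, intron_window=config.intron_window,
        epsilon=config.epsilon,
    )
    prof = pd.concat(
        [p5.as_frame().assign(boundary_kind="5ss"), p3.as_frame().assign(boundary_kind="3ss")],
        ignore_index=True,
    )
    io.write_table(prof, record(out / "boundary_profiles.tsv"))

    if ip2 is not None:
        r, n = rna_map.replicate_correlation(ip, ip2, min_depth=config.min_depth)
        io.write_table([{"pair": "ip_rep1_vs_ip_rep2", "pearson_r": r, "n_positions": n}],
                       record(out / "replicate_correlation.tsv"))

    if events:
        classified = splice.classify_events(events, config.dpsi_threshold, config.fdr_threshold)
        by_class = splice.events_by_class(classified)
        maps = rna_map.composite_map(merged, by_class, n_bins=config.n_bins, bin_mode=config.bin_mode)
        rows = []
        for cm in maps:
            for b, occ in enumerate(cm.occupancy):
                rows.append({"event_class": cm.event_class, "bin": b, "occupancy": occ,
                             "n_events": cm.n_events})
        io.write_table(pd.DataFrame(rows), record(out / "composite_maps.tsv"))


@_wrap("splice_stats")
def _stage_splice_stats(config, models, genome, merged, events, planted, out, record, stage, notes):
    stage("splice_stats")
    classified = splice.classify_events(events, config.dpsi_threshold, config.fdr_threshold)
    io.write_table(
        (
            {
                "event_id": ce.event.event_id, "gene_id": ce.event.gene_id,
                "event_type": ce.event.event_type, "delta_psi": ce.event.delta_psi,
                "fdr": ce.event.fdr, "responsiveness": ce.responsiveness,
            }
            for ce in classified
        ),
        record(out / "classified_events.tsv"), sort_by=["event_id"],
    )
    io.write_table(splice.class_proportions(classified, by="event_type"),
                   record(out / "class_proportions_by_type.tsv"))
    io.write_table(splice.class_proportions(classified, by="responsiveness"),
                   record(out / "class_proportions_by_responsiveness.tsv"))

    if merged is not None:
        inter = splice.intersect_peaks_events(merged, models, events, flank_nt=config.flank_nt)
        inter = {k: v for k, v in inter.items() if k != "genes_in_both"}
        io.write_table([inter], record(out / "intersection_summary.tsv"))

    feats = splice.architecture_features(classified)
    io.write_table(feats, record(out / "architecture_features.tsv"), sort_by=["event_id"])
    io.write_table(splice.architecture_comparison(feats), record(out / "architecture_tests.tsv"))

    if genome:
        scorer = splice.PwmScorer.train(models, genome)
        by_class = splice.events_by_class(classified)
        windows_by_class = {
            cls: splice.extract_splice_site_windows(evs, genome)
            for cls, evs in by_class.items() if evs
        }
        comparison = splice.score_splice_sites(windows_by_class, scorer)
        io.write_table(comparison.scores, record(out / "splice_site_scores.tsv"),
                       sort_by=["event_id", "site_role", "class"])
        io.write_table(comparison.tests, record(out / "splice_site_tests.tsv"))
    else:
        notes["splice_sites"] = "skipped: no genome sequence"


@_wrap("enrichment")
def _stage_enrichment(config, models, out, record, stage, notes):
    stage("enrichment")
    sim = config.simulation
    if "gaf" in config.inputs:
        assoc = io.read_gaf(config.inputs["gaf"])
        gene_list = set(config.inputs.get("gene_list", []))
    elif sim is not None:
        assoc, gene_list, _ = synthetic.simulate_go(models, sim)
        io.write_gaf(assoc, record(out / "associations.gaf"))
        assoc = io.read_gaf(out / "associations.gaf")
    else:
        notes["go"] = "skipped: no GO input"
        assoc, gene_list = [], set()
    if assoc and gene_list:
        background = {m.gene_id for m in models} or {a.gene_id for a in assoc}
        results = enr.go_enrichment(gene_list, background, assoc, min_term_size=config.min_term_size)
        io.write_table(enr.enrichment_table(results), record(out / "go_enrichment.tsv"))

    if "complexes" in config.inputs:
        cplx = config.inputs["complexes"]
        scores = config.inputs["protein_scores"]
    elif sim is not None:
        cplx, scores, _ = synthetic.simulate_complexes(sim)
        io.write_table(
            ({"complex_id": c, "member": m} for c, members in sorted(cplx.items()) for m in members),
            record(out / "complexes.tsv"),
        )
        io.write_table(
            ({"protein": p, "score": s} for p, s in sorted(scores.items())),
            record(out / "protein_scores.tsv"),
        )
    else:
        notes["complexes"] = "skipped: no proteomics input"
        return
    results = enr.complex_enrichment(
        scores, cplx, n_perm=config.n_perm, seed=config.seed, p_cutoff=config.complex_p_cutoff
    )
    io.write_table(enr.ranked_curve_table(results), record(out / "complex_ranked_curve.tsv"))
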