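"""End-to-end orchestration: simulate -> preprocess -> cluster -> map ->
select -> report, with per-stage artifacts, seeds and checksums recorded
in a run manifest so deterministic stages are byte-reproducible."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from . import preprocess as pp
from .clustering import (
    RepeatCluster,
    build_similarity_graph,
    cluster_reads,
    clusters_table,
    summary_table,
)
from .config import PipelineConfig
from .enrichment import (
    MapperConfig,
    compute_enrichment,
    enrichment_report,
    map_reads_to_clusters,
    mean_enrichment,
    select_candidates,
)
from .reads import ReadSet
from .simulate import OccupancyModel, simulate_chip_input, simulate_wgs_reads
from .util import derive_seed, sha256_file

__version__ = "0.1.0"

log = logging.getLogger("censkim")


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seeds: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run (artifacts are also on disk)."""

    manifest: RunManifest
    clusters: list[RepeatCluster]
    summary: "pd.DataFrame"
    records: list
    report: pd.DataFrame
    truth_composition: pd.DataFrame
    mean_ratio: float | None


def _truth_composition(clusters: list[RepeatCluster], rs: ReadSet) -> pd.DataFrame:
    """Per-cluster ground-truth family composition (simulated reads only)."""
    by_id = rs.by_id()
    rows = []
    for c in clusters:
        fams: dict[str, int] = {}
        for rid in c.member_reads:
            src = by_id[rid].source
            fam = src.family if src and src.family else "background"
            fams[fam] = fams.get(fam, 0) + 1
        top_family = max(fams, key=lambda f: (fams[f], f))
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "size": c.size,
                "top_family": top_family,
                "top_family_fraction": fams[top_family] / c.size,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the sequencing arm of the pipeline on a synthetic genome.

    Stages: genome simulation, WGS read simulation, preprocessing
    (quality filter, trim, interlace, coverage subsampling), similarity
    clustering, ChIP/input simulation, cluster mapping, enrichment and
    candidate selection.  Artifacts are persisted under ``config.outdir``.
    """
    outdir = cio.ensure_dir(config.outdir)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    manifest = RunManifest(config=config.to_dict())

    def stage_seed(name: str) -> int:
        s = derive_seed(config.seed, name)
        manifest.seeds[name] = s
        return s

    # --- simulate genome ------------------------------------------------
    genome_spec = config.genome.genome_spec(stage_seed("genome"))
    from .simulate import build_genome  # local import keeps module load light

    genome = build_genome(genome_spec)
    log.info("genome: %d bp, %d annotations", genome.genome_length, len(genome.annotations))
    fasta = outdir / "genome.fasta"
    cio.write_fasta(fasta, list(genome.sequences.items()))
    bed = outdir / "annotations.bed"
    cio.write_bed(
        bed,
        [(a.chrom, a.start, a.end, f"{a.family}:{a.subfamily}") for a in genome.annotations],
    )
    cen_bed = outdir / "centromeres.bed"
    cio.write_bed(cen_bed, [(c, s, e, "centromere") for c, s, e in genome.centromeres])

    # --- WGS reads + preprocessing ---------------------------------------
    wgs = simulate_wgs_reads(
        genome,
        coverage=config.wgs.coverage * config.wgs.oversample_factor,
        read_length=config.wgs.read_length,
        paired=config.wgs.paired,
        seed=stage_seed("wgs"),
        quality=config.wgs.quality,
        error_rate=config.wgs.error_rate,
    )
    rs = pp.trim_adapters(wgs, config.preprocess.adapter_prefix, config.preprocess.adapter_suffix)
    rs = pp.quality_filter(rs, config.preprocess.quality_cutoff, config.preprocess.pass_fraction)
    rs = pp.trim_to_length(rs, config.preprocess.trim_length)
    if config.wgs.paired:
        rs = pp.interlace_pairs(rs)
    rs = pp.subsample_to_coverage(
        rs,
        genome_length=genome.genome_length,
        target_coverage=config.wgs.coverage,
        read_length=config.wgs.read_length,
        seed=stage_seed("subsample"),
    )
    log.info("preprocessed WGS reads: %d", len(rs))
    cio.write_fastq(outdir / "wgs_preprocessed.fastq", rs)

    # --- clustering -------------------------------------------------------
    edges = build_similarity_graph(
        rs, config.cluster.min_identity, config.cluster.min_overlap_fraction
    )
    clusters, summary = cluster_reads(edges, rs)
    log.info(
        "clusters: %d (%.2f%% of reads clustered)",
        summary.n_clusters,
        100 * summary.clustered_fraction,
    )
    cio.write_tsv(outdir / "clusters.tsv", clusters_table(clusters))
    cio.write_tsv(outdir / "clustering_summary.tsv", summary_table(summary))
    truth = _truth_composition(clusters, rs)
    cio.write_tsv(outdir / "cluster_truth_composition.tsv", truth)

    # --- ChIP / input -----------------------------------------------------
    model = OccupancyModel(
        family_weights=dict(config.chip.family_weights),
        background_weight=config.chip.background_weight,
        occupied_fraction=config.chip.occupied_fraction,
    )
    chip, inp = simulate_chip_input(
        genome,
        model,
        n_reads=config.chip.n_reads,
        read_length=config.wgs.read_length,
        seed=stage_seed("chip"),
        quality=config.wgs.quality,
        error_rate=config.wgs.error_rate,
    )
    cio.write_fastq(outdir / "chip.fastq", chip)
    cio.write_fastq(outdir / "input.fastq", inp)

    # --- mapping, enrichment, selection ----------------------------------
    mcfg = MapperConfig(
        n_sampled_reads=config.chip.n_reads,
        bit_score_threshold=config.mapper.bit_score_threshold,
        top_n_clusters=config.mapper.top_n_clusters,
        max_candidates=config.mapper.max_candidates,
    )
    chip_counts = map_reads_to_clusters(chip, clusters, mcfg)
    input_counts = map_reads_to_clusters(inp, clusters, mcfg)
    records = compute_enrichment(chip_counts, input_counts, mcfg)
    try:
        mean_ratio = mean_enrichment(records)
    except ValueError:
        mean_ratio = None
    report = enrichment_report(records, clusters, mcfg, config.mapper.precedence)
    cio.write_tsv(outdir / "enrichment_report.tsv", report)
    all_records = pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "chip_hits": r.chip_hits,
                "input_hits": r.input_hits,
                "ratio": r.ratio if r.ratio is not None else "NA",
            }
            for r in records
        ]
    )
    cio.write_tsv(outdir / "enrichment_records.tsv", all_records)

    for artifact in sorted(outdir.iterdir()):
        if artifact.is_file() and artifact.name != "manifest.json":
            manifest.checksums[artifact.name] = sha256_file(artifact)
    manifest.write(outdir / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        clusters=clusters,
        summary=summary_table(summary),
        records=records,
        report=report,
        truth_composition=truth,
        mean_ratio=mean_ratio,
    )


def selected_cluster_ids(result: PipelineResult) -> set[str]:
    cfg = MapperConfig(n_sampled_reads=result.manifest.config["chip"]["n_reads"])
    high, enr = select_candidates(result.records, cfg)
    return {r.cluster_id for r in high} | {r.cluster_id for r in enr}
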