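"""End-to-end orchestration: synthesis -> demux -> quantification ->
novelty -> VJ detection, with a JSON report and a run manifest.

A run is described by two blocks of configuration: ``thresholds``
(:class:`~sciso.config.PipelineConfig`, every analysis threshold) and
``simulation`` (:class:`SimulationParams`, the synthetic experiment).
All stage outputs are written under one output directory; the manifest
records the config snapshot, input-file digests, per-stage record counts
and the seed, so that a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ConfigError, DEFAULT_CONFIG, PipelineConfig
from .demux import DemuxResult, demultiplex, write_demux_fastq, write_demux_tsv
from .gtf import write_gtf
from .igdetect import build_segment_index, detect_vj, presence_matrix
from .isoquant import (
    JunctionIndex,
    assign_read,
    biotype_composition,
    build_matrix,
    cluster_profiles,
    dedup_umi,
    parse_alignments,
    per_cell_summary,
    snap_junctions,
    write_matrix_10x,
)
from .models import FULL_SPLICE_MATCH, INCOMPLETE_SPLICE_MATCH
from .novelty import (
    assess_coding,
    classify_novel_transcripts,
    confirm_novel_exons,
    detect_insert_candidates,
    filter_novel_transcripts,
    remove_matched_antisense,
    write_novel_exon_bed,
    write_novel_transcripts_tsv,
)
from .synth import (
    SyntheticTruth,
    generate_annotation,
    generate_cells,
    make_ig_segments,
    plant_novel_exons,
    simulate_ig_molecules,
    simulate_long_reads,
    write_fasta,
    write_fastq,
    write_truth_sam,
    write_whitelist,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationParams:
    """The synthetic experiment: sizes, rates and planted events.

    Defaults emulate a desk-scale version of a 10x + long-read study:
    1% substitution errors, and 5' truncation of 80% of molecules by up
    to 65% of their length (mean transcript coverage ~74%).
    """

    n_genes: int = 30
    max_isoforms_per_gene: int = 3
    noncoding_fraction: float = 0.15
    n_cells: int = 200
    n_clusters: int = 5
    n_samples: int = 4
    concentration: float = 1.0
    molecules_per_cell: int = 50
    error_rate: float = 0.01
    truncation_prob: float = 0.8
    trunc_max_frac: float = 0.65
    n_novel_exons: int = 5
    novel_exon_len: tuple[int, int] = (21, 300)
    novel_exon_support: tuple[int, int] = (2, 5)
    n_ig_molecules: int = 30
    n_v_segments: int = 3
    n_j_segments: int = 2
    seed: int = 42

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("novel_exon_len", "novel_exon_support"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: Union[str, Path]) -> tuple[PipelineConfig, SimulationParams]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.from_dict(raw.get("thresholds", {}))
    sim = SimulationParams.from_dict(raw.get("simulation", {}))
    return cfg, sim


@dataclass
class RunResult:
    outdir: Path
    config: PipelineConfig
    sim: SimulationParams
    truth: SyntheticTruth
    demux: DemuxResult
    assignments: list
    molecules: pd.DataFrame
    adata: "object"
    novel_exon_calls: list
    novel_transcripts: list
    novel_transcripts_retained: list
    vj_calls: list
    report: dict
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _child_seed(seed: int, offset: int) -> int:
    return (seed * 1000 + offset) % (2**31 - 1)


def synthesize(
    sim: SimulationParams, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[SyntheticTruth, list, dict[str, dict[str, str]]]:
    """Generate the full synthetic dataset; returns (truth, reads, segments)."""
    truth = generate_annotation(
        sim.n_genes,
        sim.max_isoforms_per_gene,
        _child_seed(sim.seed, 1),
        noncoding_fraction=sim.noncoding_fraction,
        config=config,
    )
    generate_cells(
        truth,
        sim.n_cells,
        sim.n_clusters,
        sim.concentration,
        _child_seed(sim.seed, 2),
        n_samples=sim.n_samples,
    )
    reads = simulate_long_reads(
        truth,
        sim.molecules_per_cell,
        sim.error_rate,
        sim.truncation_prob,
        _child_seed(sim.seed, 3),
        trunc_max_frac=sim.trunc_max_frac,
    )
    if sim.n_novel_exons:
        reads += plant_novel_exons(
            truth,
            sim.n_novel_exons,
            sim.novel_exon_len,
            sim.novel_exon_support,
            _child_seed(sim.seed, 4),
            error_rate=sim.error_rate,
        )
    vs, js, c = make_ig_segments(sim.n_v_segments, sim.n_j_segments, _child_seed(sim.seed, 5))
    if sim.n_ig_molecules:
        reads += simulate_ig_molecules(
            truth, vs, js, c, sim.n_ig_molecules, _child_seed(sim.seed, 6), error_rate=sim.error_rate
        )
    segments = {"V": vs, "J": js, "C": {"IGKC": c}}
    return truth, reads, segments


def run(
    config: Union[str, Path, PipelineConfig, None] = None,
    outdir: Union[str, Path] = "sciso_out",
    sim: Optional[SimulationParams] = None,
) -> RunResult:
    """Run the full pipeline on a synthetic dataset.

    ``config`` may be a YAML file (with ``thresholds`` and ``simulation``
    blocks), a :class:`PipelineConfig`, or None for defaults.
    """
    write_files = True
    if isinstance(config, (str, Path)):
        cfg, sim_loaded = load_config(config)
        sim = sim if sim is not None else sim_loaded
    else:
        cfg = config if config is not None else DEFAULT_CONFIG
        sim = sim if sim is not None else SimulationParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": sim.seed,
        "config": {"thresholds": cfg.to_dict(), "simulation": dataclasses.asdict(sim)},
        "stages": {},
        "inputs": {},
    }

    # --- stage 1: synthesis -------------------------------------------------
    truth, reads, segments = synthesize(sim, cfg)
    logger.info("synth: %d molecules, %d planted exons, %d Ig molecules",
                len(truth.molecule_log), len(truth.planted_novel_exons), len(truth.planted_vj))
    manifest["stages"]["synth"] = {
        "n_reads": len(reads),
        "n_molecules": len(truth.molecule_log),
        "n_transcripts": len(truth.annotation),
        "n_planted_exons": len(truth.planted_novel_exons),
        "n_ig_molecules": len(truth.planted_vj),
    }

    fastq = outdir / "reads.fastq"
    genome_sam = outdir / "truth_genome.sam"
    tx_sam = outdir / "truth_transcriptome.sam"
    if write_files:
        write_fastq(reads, fastq)
        write_fasta(truth.genome, outdir / "genome.fa")
        write_gtf(truth.annotation, outdir / "annotation.gtf")
        write_whitelist(truth, outdir / "whitelist.tsv")
        write_truth_sam(reads, truth, genome_sam, "genome")
        write_truth_sam(reads, truth, tx_sam, "transcriptome")
        for cls in ("V", "J", "C"):
            write_fasta(segments[cls], outdir / f"ig_{cls}.fa")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "planted_novel_exons": [dataclasses.asdict(e) for e in truth.planted_novel_exons],
                    "planted_vj": truth.planted_vj,
                    "isoform_events": truth.isoform_events,
                    "cells": {b: dataclasses.asdict(c) for b, c in truth.cells.items()},
                },
                fh,
                indent=1,
            )
        for f in ("reads.fastq", "genome.fa", "annotation.gtf", "whitelist.tsv"):
            manifest["inputs"][f] = _sha256(outdir / f)

    # --- stage 2: demultiplexing ---------------------------------------------
    read_pairs = [(r.read_id, r.seq) for r in reads]
    dres = demultiplex(read_pairs, sorted(truth.cells), cfg)
    if write_files:
        write_demux_fastq(dres, outdir / "demux.fastq")
        write_demux_tsv(dres, outdir / "demux.tsv")
    manifest["stages"]["demux"] = dict(dres.summary)
    logger.info("demux: %s of %s reads assigned", dres.summary["n_assigned"], dres.summary["n_reads"])

    # --- stage 3: isoform quantification -------------------------------------
    genome_alns, g_counts = parse_alignments(genome_sam, "genome")
    tx_alns, t_counts = parse_alignments(tx_sam, "transcriptome")
    jindex = JunctionIndex(truth.annotation)
    genome_alns = [snap_junctions(a, jindex, cfg.microindel_max) for a in genome_alns]
    by_read: dict[str, list] = {}
    for a in genome_alns:
        by_read.setdefault(a.read_id, []).append(a)
    demux_by_id = dres.records_by_id()
    assignments, assign_pairs = [], []
    for rid, alns in sorted(by_read.items()):
        rec = demux_by_id.get(rid)
        if rec is None or rec.barcode is None:
            continue  # only demux-assigned reads are quantified
        a = assign_read(alns, truth.annotation, cfg, rec)
        assignments.append(a)
        assign_pairs.append((a, alns[0]))
    molecules = dedup_umi(assignments)
    cluster_labels = {b: c.cluster for b, c in truth.cells.items()}
    adata = build_matrix(
        molecules,
        cluster_labels,
        transcripts=sorted(truth.annotation.transcripts),
        gene_of_transcript={t.transcript_id: t.gene_id for t in truth.annotation},
    )
    cl_totals, freqs = cluster_profiles(adata)
    per_cell, medians = per_cell_summary(adata, molecules)
    condition_of = {b: c.condition for b, c in truth.cells.items()}
    fractions, tests = biotype_composition(molecules, truth.annotation, condition_of)
    if write_files:
        write_matrix_10x(adata, outdir / "matrix")
        freqs.to_csv(outdir / "cluster_isoform_frequencies.tsv", sep="\t", index=False)
        cl_totals.to_csv(outdir / "cluster_totals.tsv", sep="\t", index=False)
        per_cell.to_csv(outdir / "per_cell_summary.tsv", sep="\t")
    manifest["stages"]["isoquant"] = {
        "alignments_parsed": g_counts,
        "n_assignments": len(assignments),
        "n_molecules": int(len(molecules)),
        "category_counts": dict(pd.Series([a.category for a in assignments]).value_counts()),
    }

    # --- stage 4: novelty -----------------------------------------------------
    candidates = detect_insert_candidates(tx_alns, truth.annotation, cfg.min_insert_len, cfg.microindel_max)
    exon_calls = confirm_novel_exons(candidates, genome_alns, truth.annotation, cfg.min_exon_support, cfg.microindel_max)
    sample_of = {b: c.sample for b, c in truth.cells.items()}
    novels = classify_novel_transcripts(assign_pairs, truth.annotation, sample_of)
    novels = remove_matched_antisense(novels, truth.annotation)
    for m in novels:
        assess_coding(m, truth.annotation, truth.genome)
    retained = filter_novel_transcripts(novels, cfg.min_transcript_reads, cfg.min_transcript_samples)
    if write_files:
        write_novel_exon_bed(exon_calls, outdir / "novel_exons.bed")
        write_novel_transcripts_tsv(novels, outdir / "novel_transcripts.tsv")
        merged = list(truth.annotation) + [m.model for m in retained]
        write_gtf(merged, outdir / "annotation_augmented.gtf")
    manifest["stages"]["novelty"] = {
        "n_insert_candidates": len(candidates),
        "n_novel_exon_calls": len(exon_calls),
        "n_novel_transcripts": len(novels),
        "n_novel_transcripts_retained": len(retained),
    }

    # --- stage 5: immunoglobulin ----------------------------------------------
    ig_index = build_segment_index(segments["V"], segments["J"], k=cfg.ig_seed_k)
    vj_calls, vj_hits = detect_vj(((r.read_id, r.seq) for r in dres.assigned), ig_index, cfg)
    seg_ids = sorted(segments["V"]) + sorted(segments["J"])
    vj_matrix, vj_cluster_counts = presence_matrix(
        vj_calls, vj_hits, seg_ids, demux_by_id, cluster_labels
    )
    if write_files:
        vj_matrix.to_csv(outdir / "vj_presence.tsv", sep="\t")
        vj_cluster_counts.rename("n_vj_reads").to_csv(outdir / "vj_cluster_counts.tsv", sep="\t")
    manifest["stages"]["igdetect"] = {"n_vj_calls": len(vj_calls)}

    # --- report ---------------------------------------------------------------
    rep = build_report(
        dres, assignments, molecules, adata, cl_totals, freqs, medians,
        fractions, tests, novels, retained, exon_calls, vj_cluster_counts,
    )
    if write_files:
        with open(outdir / "report.json", "w") as fh:
            json.dump(rep, fh, indent=1, default=str)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    return RunResult(
        outdir=outdir, config=cfg, sim=sim, truth=truth, demux=dres,
        assignments=assignments, molecules=molecules, adata=adata,
        novel_exon_calls=exon_calls, novel_transcripts=novels,
        novel_transcripts_retained=retained, vj_calls=vj_calls,
        report=rep, manifest=manifest,
    )


def _fraction(num: int, den: int) -> dict:
    return {"numerator": int(num), "denominator": int(den), "value": (num / den if den else None)}


def build_report(
    demux_result,
    assignments,
    molecules,
    adata,
    cluster_totals,
    frequencies,
    medians,
    biotype_fractions,
    biotype_tests,
    novel_transcripts,
    retained,
    exon_calls,
    vj_cluster_counts,
) -> dict:
    """Assemble the summary statistics of a run; every fraction carries
    its numerator and denominator, and undefined ratios are null."""
    cat_counts = pd.Series([a.category for a in assignments]).value_counts() if assignments else pd.Series(dtype=int)
    # genes with >= 2 isoforms each backed by >= 1 molecule
    if len(molecules):
        iso_per_gene = molecules.groupby("gene_id")["transcript_id"].nunique()
        genes_detected = int((iso_per_gene >= 1).sum())
        genes_multi = int((iso_per_gene >= 2).sum())
    else:
        genes_detected = genes_multi = 0
    per_cluster_mol = (
        {str(r["cluster"]): int(r["total_molecules"]) for _, r in cluster_totals.iterrows()}
        if len(cluster_totals)
        else {}
    )
    event_counts = pd.Series([m.event for m in novel_transcripts]).value_counts() if novel_transcripts else pd.Series(dtype=int)
    coding_counts = pd.Series(
        ["unknown" if m.coding is None else ("coding" if m.coding else "noncoding") for m in novel_transcripts]
    ).value_counts() if novel_transcripts else pd.Series(dtype=int)

    return {
        "reads": {
            "total": demux_result.summary["n_reads"],
            "fraction_assigned_to_cells": _fraction(
                demux_result.summary["n_assigned"], demux_result.summary["n_reads"]
            ),
            "demux_status_counts": demux_result.summary["per_status"],
        },
        "assignment_category_counts": {k: int(v) for k, v in cat_counts.items()},
        "molecules": {
            "total": int(len(molecules)),
            "reads_backing_molecules": int(molecules["support"].sum()) if len(molecules) else 0,
        },
        "per_cluster_molecules": per_cluster_mol,
        "per_cell_medians": medians,
        "multi_isoform_genes": _fraction(genes_multi, genes_detected),
        "novel_exons": {"n_calls": len(exon_calls)},
        "novel_transcripts": {
            "n_models": len(novel_transcripts),
            "n_retained": len(retained),
            "by_event": {k: int(v) for k, v in event_counts.items()},
            "coding_status": {k: int(v) for k, v in coding_counts.items()},
        },
        "biotype_fractions_by_condition": (
            {str(c): {b: float(v) for b, v in row.items()} for c, row in biotype_fractions.iterrows()}
            if len(biotype_fractions)
            else {}
        ),
        "biotype_tests": (biotype_tests.to_dict(orient="records") if biotype_tests is not None else None),
        "vj_reads_per_cluster": {str(k): int(v) for k, v in vj_cluster_counts.items()},
    }
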