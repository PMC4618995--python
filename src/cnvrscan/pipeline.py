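"""End-to-end orchestration: count -> normalize -> segment -> call -> validate.

A single :class:`PipelineConfig` carries every stage parameter with the
defaults used throughout the package (3,000-bp windows, MAPQ >= 20, >50% N
removal, 0.01 GC bins, trimmed-SD threshold 0.25, 10,000 permutations,
aberrant-BAF ranges [0.05, 0.35] and [0.65, 0.95] with a 10% carrier rule,
70% gene-overlap rule, 10-kb flanks). One global seed deterministically
derives all per-stage streams, so re-running a config reproduces identical
artifacts.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as cio
from .baf import BAFConfig, classify_aberrant, cnvr_baf_tests, filter_snps
from .calling import (CNVRSet, call_cnvrs, empirical_fdr, summarize_cnvrs,
                      trimmed_sd_track)
from .enrichment import (class_enrichment, flanking_regions, gene_overlap,
                         go_enrichment, RegionSet, regions_from_features,
                         repeat_enrichment)
from .errors import CnvrScanError, InvalidParameterError
from .normalize import GCAdjustConfig, gc_adjust, standardize
from .segment import SegConfig, scores_from_segments, segment_cohort
from .windows import (DepthMatrix, FilterConfig, WindowGrid, apply_exclusion_masks,
                      assemble_cohort, build_windows, count_reads)

log = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.65, 0.05), 2))


@dataclass
class PipelineConfig:
    # inputs (either alignments+reference or a precomputed count matrix)
    alignments: List[str] = field(default_factory=list)
    reference: Optional[str] = None
    count_matrix: Optional[str] = None
    grid_file: Optional[str] = None
    exclusion_beds: List[str] = field(default_factory=list)
    features_file: Optional[str] = None
    repeats_file: Optional[str] = None
    baf_file: Optional[str] = None
    go_map_file: Optional[str] = None
    # stage parameters
    window_size: int = 3000
    mapq_min: int = 20
    n_fraction_max: float = 0.5
    gc_bin_width: float = 0.01
    gc_min_windows: int = 10
    seg_alpha: float = 0.01
    seg_permutations: int = 100
    seg_min_width: int = 2
    tsd_threshold: float = 0.25
    fdr_permutations: int = 10_000
    fdr_ceiling: float = 0.15
    baf_lo: float = 0.05
    baf_hi: float = 0.35
    baf_lo2: float = 0.65
    baf_hi2: float = 0.95
    baf_min_fraction: float = 0.10
    gene_overlap_fraction: float = 0.70
    flank_bp: int = 10_000
    seed: int = 0
    outdir: str = "cnvrscan_out"

    def validate(self):
        checks = [
            (self.window_size > 0, "window_size must be positive"),
            (self.mapq_min >= 0, "mapq_min must be >= 0"),
            (0 < self.n_fraction_max <= 1, "n_fraction_max in (0, 1]"),
            (0 < self.gc_bin_width <= 1, "gc_bin_width in (0, 1]"),
            (0 < self.seg_alpha < 1, "seg_alpha in (0, 1)"),
            (self.tsd_threshold >= 0, "tsd_threshold must be >= 0"),
            (self.fdr_permutations >= 1, "fdr_permutations >= 1"),
            (0 < self.gene_overlap_fraction < 1, "gene_overlap_fraction in (0, 1)"),
            (self.flank_bp >= 0, "flank_bp >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidParameterError(msg)


def _checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: PipelineConfig):
    """Build the grid and raw cohort matrix from whichever inputs are given."""
    if config.count_matrix:
        if not config.grid_file:
            raise InvalidParameterError("count_matrix input requires grid_file")
        grid = cio.read_grid(config.grid_file)
        matrix = cio.read_matrix(config.count_matrix, stage="raw")
        return grid, matrix
    if not config.alignments or not config.reference:
        raise InvalidParameterError(
            "provide either count_matrix+grid_file or alignments+reference")
    import pyfaidx
    ref = pyfaidx.Fasta(config.reference)
    chrom_lengths = {name: len(ref[name]) for name in ref.keys()}
    grid = build_windows(chrom_lengths, config.window_size, reference=ref,
                         n_fraction_max=config.n_fraction_max)
    for bed in config.exclusion_beds:
        grid = apply_exclusion_masks(grid, cio.read_bed(bed))
    fc = FilterConfig(mapq_min=config.mapq_min, window_size=config.window_size,
                      n_fraction_max=config.n_fraction_max)
    singles = [count_reads(path, grid, fc) for path in config.alignments]
    return grid, assemble_cohort(singles)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write TSV/BED artifacts plus a manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    manifest = {"config": asdict(config), "stages": [], "inputs": {}}
    for path in ([config.count_matrix, config.grid_file, config.reference,
                  config.features_file, config.repeats_file, config.baf_file,
                  config.go_map_file] + config.alignments + config.exclusion_beds):
        if path and os.path.exists(str(path)):
            manifest["inputs"][str(path)] = _checksum(path)

    artifacts: Dict[str, object] = {}

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            with open(out("INCOMPLETE"), "w") as fh:
                fh.write(f"failed at stage {name}: {exc}\n")
            raise CnvrScanError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)
        return result

    grid, raw = stage("count", lambda: _load_inputs(config))
    artifacts["grid"], artifacts["raw"] = grid, raw
    cio.write_grid(grid, out("window_grid.tsv"), {"stage": "count"})
    cio.write_matrix(raw, out("counts_raw.tsv"))

    gcc = GCAdjustConfig(config.gc_bin_width, config.gc_min_windows)
    adjusted = stage("normalize", lambda: gc_adjust(raw, grid, gcc))
    std = stage("standardize", lambda: standardize(adjusted))
    artifacts["standardized"] = std
    cio.write_matrix(std, out("counts_standardized.tsv"))

    seg_cfg = SegConfig(alpha=config.seg_alpha,
                        n_permutations=config.seg_permutations,
                        min_width=config.seg_min_width, seed=config.seed)
    profile = stage("segment", lambda: segment_cohort(std, grid, seg_cfg))
    scores = stage("scores", lambda: scores_from_segments(
        profile, grid, samples=std.samples))
    artifacts["profile"], artifacts["scores"] = profile, scores
    seg_rows = []
    retained = grid.retained.reset_index(drop=True)
    for (sample, chrom), entry in profile.entries.items():
        for lo, hi, sc in entry.segments:
            seg_rows.append((sample, chrom,
                             int(retained["start"].iloc[entry.rows[lo]]),
                             int(retained["end"].iloc[entry.rows[hi]]),
                             hi - lo + 1, sc))
    cio.write_tsv(pd.DataFrame(seg_rows, columns=["sample", "chrom", "start_bp",
                                                  "end_bp", "n_windows", "score"]),
                  out("segments.tsv"))
    cio.write_tsv(scores.reset_index(), out("segmentation_scores.tsv"))

    track = stage("trimmed_sd", lambda: trimmed_sd_track(scores))
    artifacts["tsd"] = track
    cio.write_tsv(pd.concat([retained[["chrom", "start", "end"]],
                             track.reset_index(drop=True)], axis=1),
                  out("trimmed_sd_track.tsv"))

    thresholds = sorted(set(DEFAULT_FDR_THRESHOLDS)
                        | ({config.tsd_threshold} if config.tsd_threshold > 0
                           else set()))
    curve = stage("fdr", lambda: empirical_fdr(
        scores, profile, grid, thresholds,
        n_permutations=config.fdr_permutations, seed=config.seed))
    artifacts["fdr"] = curve
    cio.write_tsv(curve.per_chrom, out("fdr_per_chromosome.tsv"))
    cio.write_tsv(curve.genome_wide, out("fdr_curve.tsv"))
    suggested = curve.threshold_at(config.fdr_ceiling)
    log.info("smallest threshold with genome-wide FDR <= %.2f: %s",
             config.fdr_ceiling, suggested)

    cnvrs = stage("call", lambda: call_cnvrs(track, grid, config.tsd_threshold))
    artifacts["cnvrs"] = cnvrs
    bed = cnvrs.regions.copy()
    if len(bed):
        bed["name"] = [f"cnvr{i + 1}" for i in range(len(bed))]
    cio.write_bed(bed, out("cnvrs.bed"), name_col="name", score_col="peak_tsd")
    summary = summarize_cnvrs(cnvrs, grid)
    summary["suggested_threshold"] = suggested
    artifacts["summary"] = summary
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)

    if config.baf_file:
        def run_baf():
            table = filter_snps(cio.read_baf(config.baf_file), grid)
            cfg = BAFConfig(config.baf_lo, config.baf_hi, config.baf_lo2,
                            config.baf_hi2, config.baf_min_fraction)
            flags = classify_aberrant(table, cfg)
            tests = cnvr_baf_tests(table, flags, cnvrs, grid)
            cio.write_tsv(pd.concat([table[["snp_id", "chrom", "pos"]],
                                     flags], axis=1), out("baf_classification.tsv"))
            report = {}
            if tests["enrichment"] is not None:
                report["enrichment"] = tests["enrichment"].as_dict()
            if tests["depletion"] is not None:
                report["depletion"] = tests["depletion"]
            with open(out("baf_tests.json"), "w") as fh:
                json.dump(report, fh, indent=2)
            return tests
        artifacts["baf"] = stage("baf", run_baf)

    if config.features_file:
        def run_annotate():
            feats = cio.read_features(config.features_file)
            genes = feats[feats["feature_class"].isin(["gene", "r_gene"])]
            in_cnvr = gene_overlap(genes, cnvrs, config.gene_overlap_fraction)
            results = {"n_genes": int(len(genes)), "n_in_cnvr": int(len(in_cnvr))}
            if (genes["feature_class"] == "r_gene").any() and len(in_cnvr):
                results["r_gene"] = class_enrichment(genes, in_cnvr, "r_gene").as_dict()
            if config.go_map_file:
                go = go_enrichment(cio.read_go_map(config.go_map_file),
                                   genes["feature_id"], in_cnvr["feature_id"])
                cio.write_tsv(go, out("go_enrichment.tsv"))
            reps = feats[feats["feature_class"].str.startswith("repeat:")]
            if config.repeats_file:
                reps = cio.read_features(config.repeats_file, default_class="repeat")
            if len(reps) and len(cnvrs):
                flanks = flanking_regions(cnvrs, grid.chrom_lengths, config.flank_bp)
                analyzed = RegionSet.from_intervals(
                    (r.chrom, r.start, r.end)
                    for r in grid.retained.itertuples())
                rep = repeat_enrichment(reps, flanks, analyzed)
                cio.write_tsv(rep, out("repeat_enrichment.tsv"))
            cio.write_tsv(in_cnvr, out("genes_in_cnvrs.tsv"))
            with open(out("annotation_tests.json"), "w") as fh:
                json.dump(results, fh, indent=2)
            return results
        artifacts["annotation"] = stage("annotate", run_annotate)

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    artifacts["manifest"] = manifest
    return artifacts


def report(artifacts: dict) -> str:
    """Human-readable run summary: region counts, lengths, genome fraction."""
    if "summary" not in artifacts:
        raise CnvrScanError("missing artifacts: run the pipeline first")
    s = artifacts["summary"]
    lines = [
        "CNVR discovery summary",
        "----------------------",
        f"regions called:        {s['count']}",
        f"total CNVR bp:         {s['total_bp']}",
        f"genome fraction:       {100 * s['genome_fraction']:.2f}%",
    ]
    if s["count"]:
        lines += [
            f"length min/median/mean/max (kb): "
            f"{s['min_bp'] / 1000:.1f} / {s['median_bp'] / 1000:.1f} / "
            f"{s['mean_bp'] / 1000:.1f} / {s['max_bp'] / 1000:.1f}",
        ]
    lines.append("per-chromosome CNVR fraction:")
    for chrom, frac in s["per_chromosome_fraction"].items():
        lines.append(f"  {chrom}: {100 * frac:.2f}%")
    if "baf" in artifacts and artifacts["baf"].get("enrichment") is not None:
        e = artifacts["baf"]["enrichment"]
        lines.append(f"aberrant-BAF enrichment: fold={e.fold:.2f} p={e.p_value:.3g}")
    return "\n".join(lines)
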