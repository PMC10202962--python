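"""End-to-end orchestration: detect, simulate, evaluate, bench.

All stages run in process; every source of randomness flows from the single
config seed, and the resolved configuration is echoed next to every output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import (
    alignment_io,
    breakpoint_bayes,
    breakpoint_graph,
    circle_search,
    enrichment,
    evaluation,
    simulator,
)
from .alignment_io import IntervalSet, ReadTable, classify_table
from .circle_search import CircleCandidate
from .evaluation import EvaluationResult, MatchCriterion
from .simulator import FragmentModel, MockEcDNA, Reference

logger = logging.getLogger("atacircle")

__all__ = ["PipelineConfig", "detect_from_table", "run_detect", "run_simulate",
           "run_evaluate", "benchmark", "desk_scale_config", "desk_scale_reference",
           "REFERENCE_SEED"]

#: seed of the bundled synthetic reference genome (fixed: the genome is part
#: of the benchmark definition, not of the per-run randomness)
REFERENCE_SEED = 20260905


def desk_scale_reference() -> "Reference":
    """The bundled ~22 Mb synthetic genome (4 contigs) used for benchmarks."""
    return Reference.synthetic(seed=REFERENCE_SEED)


def desk_scale_config(seed: int, read_len: int = 100) -> "PipelineConfig":
    """The scaled-down mock-ecDNA benchmark: 5 samples x 5 circles of 1-8
    segments (20-200 kb each) at 30x local depth over 2x linear background."""
    return PipelineConfig(
        seed=seed,
        n_samples=5,
        n_ecdna=5,
        n_segments=(1, 8),
        segment_size=(20_000, 200_000),
        read_len=read_len,
        local_depth=30.0,
        background_depth=2.0,
    )


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the documented defaults."""

    # read filtering / classification
    mapq_min: int = 10
    insert_threshold: int = 1500
    inter_contig_discordant: bool = True
    blacklist_mode: str = "any"
    # enrichment
    p_cut: float = 0.05
    merge_dist: int = 12_500
    min_peak_len: int = enrichment.DEFAULT_MIN_PEAK_LEN
    disc_score_cut: float = enrichment.DEFAULT_SCORE_CUT
    disc_max_gap: int = enrichment.DEFAULT_MAX_GAP
    disc_count_mode: bool = False
    lambda_mode: str = "exclude-peaks"  # or 'global'
    # graph
    min_support: Optional[int] = None  # None -> Poisson inverse-survival default
    min_support_floor: int = 3
    # breakpoint model
    e: float = 5.0
    # search + filters
    max_outputs: int = 1000
    fold_min: float = 10.0
    support_min: int = 3
    max_repeat_frac: float = 0.05
    # simulation
    seed: int = 0
    read_len: int = 100
    local_depth: float = 30.0
    background_depth: float = 2.0
    n_ecdna: int = 20
    n_samples: int = 1
    n_segments: tuple[int, int] = (1, 8)
    segment_size: Optional[tuple[int, int]] = (20_000, 200_000)
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    fragment_max: int = 1000
    error_rate: float = 0.0
    min_align: int = simulator.DEFAULT_MIN_ALIGN
    # io
    bam: Optional[str] = None
    blacklist: Optional[str] = None
    repeats: Optional[str] = None
    reference: Optional[str] = None
    out_dir: str = "atacircle_out"
    threads: int = 1  # I/O only; never affects results

    def __post_init__(self) -> None:
        if self.mapq_min < 0 or self.insert_threshold <= 0:
            raise ValueError("mapq_min must be >= 0 and insert_threshold > 0")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must be in (0, 1)")
        if self.merge_dist < 0 or self.max_outputs < 1:
            raise ValueError("merge_dist must be >= 0 and max_outputs >= 1")
        if self.lambda_mode not in ("exclude-peaks", "global"):
            raise ValueError(f"unknown lambda_mode: {self.lambda_mode}")
        if self.e <= 0 or self.support_min < 0:
            raise ValueError("e must be > 0 and support_min >= 0")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Plain key=value config file; '#' starts a comment."""
        mapping: dict = {}
        hints = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                key, raw = (part.strip() for part in line.split("=", 1))
                mapping[key] = _coerce(raw)
        return cls.from_mapping(mapping)

    def echo(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
            fh.write("\n")


def _coerce(raw: str):
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", "null", ""):
        return None
    if "," in raw:
        return tuple(_coerce(part.strip()) for part in raw.split(","))
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


@dataclass
class DetectionResult:
    candidates: list[CircleCandidate]
    all_circles: list[CircleCandidate]
    info: dict = field(default_factory=dict)


def detect_from_table(table: ReadTable, config: PipelineConfig) -> DetectionResult:
    """Run the staged detection pipeline on an in-memory read table."""
    blacklist = (
        IntervalSet.from_bed(config.blacklist) if config.blacklist else IntervalSet()
    )
    info: dict = {"n_reads": len(table)}
    disc_mask, clip_mask = classify_table(
        table, config.insert_threshold, config.inter_contig_discordant
    )
    info["n_discordant_reads"] = int(disc_mask.sum())
    logger.info("[classify] %d reads, %d discordant", len(table), info["n_discordant_reads"])

    tracks = enrichment.pileup(table, table.contig_lengths)
    lam = enrichment.genome_lambda(tracks, blacklist)
    consec = enrichment.call_consecutive_regions(
        tracks, lam, config.p_cut, config.merge_dist, config.min_peak_len
    )
    if config.lambda_mode == "exclude-peaks" and consec:
        lam = enrichment.genome_lambda(tracks, blacklist, exclude=consec)
        consec = enrichment.call_consecutive_regions(
            tracks, lam, config.p_cut, config.merge_dist, config.min_peak_len
        )
    info["lambda"] = lam
    info["n_consecutive_regions"] = len(consec)
    logger.info("[enrich] lambda=%.4f, %d consecutive regions", lam, len(consec))

    if info["n_discordant_reads"] == 0:
        logger.info("[enrich] no discordant reads; no candidates")
        return DetectionResult([], [], info)
    disc_tracks = enrichment.pileup(table, table.contig_lengths, mask=disc_mask)
    disc_regions = enrichment.call_discordant_regions(
        disc_tracks,
        tracks,
        reads=table,
        disc_mask=disc_mask,
        score_cut=config.disc_score_cut,
        max_gap=config.disc_max_gap,
        count_mode=config.disc_count_mode,
        exclude=consec if config.lambda_mode == "exclude-peaks" else (),
    )
    disc_regions = enrichment.attach_to_consecutive(disc_regions, consec)
    info["n_discordant_regions"] = len(disc_regions)
    logger.info("[enrich] %d discordant regions after attachment", len(disc_regions))

    graph = breakpoint_graph.build_graph(disc_regions)
    if config.min_support is None:
        counts = [len(d.supporting_read_ids) for d in disc_regions]
        # rate of the enrichment-stage Poisson model: discordant mass per
        # covered base, a small number, so the floor usually decides
        covered = sum(len(t.values) for t in tracks.values())
        lam_disc = max(sum(counts) / max(covered, 1), 1e-12)
        min_support = breakpoint_graph.min_support_default(
            lam_disc, config.p_cut, config.min_support_floor
        )
    else:
        min_support = config.min_support
    info["min_support"] = min_support
    breakpoint_graph.add_discordant_edges(graph, table, disc_mask, min_support)
    breakpoint_bayes.apply_estimates(
        graph, table, disc_mask, clip_mask, e=config.e,
        insert_threshold=config.insert_threshold,
    )
    breakpoint_graph.add_consecutive_edges(graph, tracks, lam)
    n_disc_edges = sum(1 for *_, d in graph.edges(data=True) if d["etype"] == "discordant")
    logger.info(
        "[graph] %d nodes, %d discordant edges (min support %d)",
        graph.number_of_nodes(), n_disc_edges, min_support,
    )

    circles = circle_search.find_circles(graph, config.max_outputs)
    repeats = IntervalSet.from_bed(config.repeats) if config.repeats else None
    kept = circle_search.apply_filters(
        circles,
        fold_min=config.fold_min,
        support_min=config.support_min,
        repeats=repeats,
        max_repeat_frac=config.max_repeat_frac,
    )
    info["n_circles"] = len(circles)
    info["n_candidates"] = len(kept)
    logger.info("[search] %d circles, %d pass filters", len(circles), len(kept))
    return DetectionResult(kept, circles, info)


def run_detect(config: PipelineConfig) -> DetectionResult:
    """Detect candidates from a BAM/SAM on disk and write the outputs."""
    if not config.bam:
        raise ValueError("config.bam is required for detect")
    os.makedirs(config.out_dir, exist_ok=True)
    blacklist = (
        IntervalSet.from_bed(config.blacklist) if config.blacklist else IntervalSet()
    )
    logger.info("[load] reading %s", config.bam)
    table = alignment_io.load_read_table(
        config.bam, blacklist=blacklist, mapq_min=config.mapq_min,
        blacklist_mode=config.blacklist_mode,
    )
    result = detect_from_table(table, config)
    bed = os.path.join(config.out_dir, "candidates.bed")
    circle_search.write_candidates_bed(result.candidates, bed)
    circle_search.write_candidates_json(
        result.candidates, os.path.join(config.out_dir, "candidates.json")
    )
    config.echo(os.path.join(config.out_dir, "config.json"))
    logger.info("[detect] wrote %d candidates to %s", len(result.candidates), bed)
    return result


def _sample_tables(
    reference: Reference,
    config: PipelineConfig,
    rng: np.random.Generator,
    sample_index: int,
) -> tuple[list[MockEcDNA], ReadTable]:
    """Simulate one blended sample: mocks + background, perfectly aligned."""
    model = FragmentModel(config.fragment_mean, config.fragment_sd, config.fragment_max)
    occupied: list = []
    mocks = []
    placements = []
    for i in range(config.n_ecdna):
        mock = simulator.generate_mock_ecdna(
            reference,
            n_segments=config.n_segments,
            segment_size=config.segment_size,
            rng=rng,
            occupied=occupied,
            mock_id=f"s{sample_index}_mock{i}",
        )
        mocks.append(mock)
        starts, lengths = simulator.simulate_fragments(
            mock, config.local_depth, config.read_len, model, rng
        )
        placements.append(
            simulator.place_pairs(
                mock, reference.contigs, starts, lengths, config.read_len, config.min_align
            )
        )
    placements.append(
        simulator.background_pairs(
            reference, config.background_depth, config.read_len, model, rng
        )
    )
    table = simulator.pairs_to_table(placements, reference.contigs, reference.lengths)
    return mocks, table


def _load_reference(config: PipelineConfig) -> Reference:
    if config.reference:
        return Reference.from_fasta(config.reference)
    return Reference.synthetic(seed=config.seed)


def run_simulate(config: PipelineConfig) -> tuple[list[MockEcDNA], str]:
    """Simulate one sample to disk (SAM + truth JSON); returns the truths."""
    os.makedirs(config.out_dir, exist_ok=True)
    reference = _load_reference(config)
    rng = np.random.default_rng(config.seed)
    mocks, table = _sample_tables(reference, config, rng, 0)
    sam_path = os.path.join(config.out_dir, "sample.sam")
    simulator.write_sam(table, sam_path)
    simulator.write_truth_json(mocks, os.path.join(config.out_dir, "truth.json"))
    config.echo(os.path.join(config.out_dir, "config.json"))
    logger.info("[simulate] %d mocks, %d reads -> %s", len(mocks), len(table), sam_path)
    return mocks, sam_path


def run_evaluate(
    config: PipelineConfig,
    predictions_json: str,
    truth_json: str,
) -> dict[str, EvaluationResult]:
    preds = circle_search.load_candidates_json(predictions_json)
    truths = simulator.load_truth_json(truth_json)
    results = {
        "coverage_structure": evaluation.score(
            preds, truths, MatchCriterion("coverage_structure")
        ),
        "breakpoint_ci_structure": evaluation.score(
            preds, truths, MatchCriterion("breakpoint_ci_structure")
        ),
    }
    os.makedirs(config.out_dir, exist_ok=True)
    evaluation.write_metrics_tsv(results, os.path.join(config.out_dir, "metrics.tsv"))
    return results


def benchmark(
    config: PipelineConfig,
    reference: Optional[Reference] = None,
    collect_ci_widths: bool = False,
) -> dict:
    """Simulate-detect-evaluate across ``config.n_samples`` samples.

    Per-sample randomness is drawn from children of the config seed so the
    sample layout is reproducible and seed-collision free.  Counts are
    pooled across samples before computing the final metrics.
    """
    reference = reference or _load_reference(config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_samples)
    totals = {
        "coverage_structure": EvaluationResult(0, 0, 0),
        "breakpoint_ci_structure": EvaluationResult(0, 0, 0),
    }
    ci_widths: list[int] = []
    all_truths = 0
    for s, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        mocks, table = _sample_tables(reference, config, rng, s)
        result = detect_from_table(table, config)
        all_truths += len(mocks)
        for mode in totals:
            totals[mode] = totals[mode] + evaluation.score(
                result.candidates, mocks, MatchCriterion(mode)
            )
        if collect_ci_widths:
            for cand in result.candidates:
                for j in cand.junctions:
                    for ci in (j.ci_a, j.ci_b):
                        if ci is not None:
                            ci_widths.append(ci[1] - ci[0])
        logger.info(
            "[bench] sample %d: %d truths, %d candidates (cov F1 so far %.3f)",
            s, len(mocks), len(result.candidates), totals["coverage_structure"].f1,
        )
    out = {"results": totals, "n_truths": all_truths}
    if collect_ci_widths:
        out["ci_widths"] = ci_widths
    return out
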