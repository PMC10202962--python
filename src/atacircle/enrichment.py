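"""Depth tracks and Poisson enrichment-region calling.

Two region classes are produced:

* consecutive enrichment regions — maximal runs of bases whose total read
  depth is significant under Poisson(genome mean depth), merged when closer
  than ``merge_dist``;
* discordant-pair enrichment regions — runs of bases whose per-base ratio of
  discordant depth to total depth is significant under Poisson(genome mean
  ratio), scored as -log10(p) against a fixed cutoff.

The survival function is extended to real-valued counts through the
gamma-Poisson duality so fractional ratios can be scored directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, special

from .alignment_io import AlignedRead, GenomicInterval, IntervalSet, ReadTable

__all__ = [
    "DEFAULT_P_CUT",
    "DEFAULT_SCORE_CUT",
    "DEFAULT_MERGE_DIST",
    "DepthTrack",
    "ConsecutiveRegion",
    "DiscordantRegion",
    "poisson_sf",
    "poisson_sf_threshold",
    "pileup",
    "genome_lambda",
    "call_consecutive_regions",
    "call_discordant_regions",
    "attach_to_consecutive",
    "write_bedgraph",
    "write_regions_bed",
]

DEFAULT_P_CUT = 0.05
#: score cutoff for the discordant ratio test, -log10 of the significance level
DEFAULT_SCORE_CUT = -math.log10(DEFAULT_P_CUT)
DEFAULT_MERGE_DIST = 12_500
#: minimum significant-run length kept before merging, mirroring the upstream
#: peak caller's minimum peak size (the fragment extension size)
DEFAULT_MIN_PEAK_LEN = 200
#: maximum gap stitched between significant discordant-ratio runs,
#: mirroring the upstream bedGraph peak caller's max-gap (about a read length)
DEFAULT_MAX_GAP = 50


def poisson_sf(count, lam):
    """P(X >= count) for X ~ Poisson(lam), continuous in ``count``.

    For integer k >= 1 this equals ``1 - sum_{i<k} exp(-lam) lam^i / i!``;
    the continuous extension is the regularised lower incomplete gamma
    function P(count, lam).  ``count == 0`` maps to 1 exactly.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lam must be positive")
    count_arr = np.asarray(count, dtype=float)
    if np.any(count_arr < 0):
        raise ValueError("count must be non-negative")
    out = np.where(count_arr > 0, special.gammainc(np.maximum(count_arr, 1e-300), lam_arr), 1.0)
    if np.isscalar(count) and np.isscalar(lam):
        return float(out)
    return out


def poisson_sf_threshold(lam: float, p_cut: float) -> float:
    """Smallest real c with poisson_sf(c, lam) < p_cut (depths above are significant)."""
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must be in (0, 1)")
    hi = lam + 20 * math.sqrt(lam) + 20
    while poisson_sf(hi, lam) >= p_cut:  # pragma: no cover - defensive
        hi *= 2
    return float(optimize.brentq(lambda c: poisson_sf(c, lam) - p_cut, 1e-12, hi))


@dataclass
class DepthTrack:
    """Dense per-base depth over one contig.

    Stored dense (int32/float64) rather than run-length encoded; contigs at
    the scales this tool targets fit comfortably and dense arrays keep the
    region calling fully vectorised.
    """

    contig: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError(f"{self.contig}: negative depth")

    def __len__(self) -> int:
        return len(self.values)

    def mean_over(self, start: int, end: int) -> float:
        return float(self.values[start:end].mean()) if end > start else 0.0


@dataclass
class ConsecutiveRegion:
    interval: GenomicInterval
    mean_depth: float
    fold_enrichment: float

    def __post_init__(self) -> None:
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be positive")


@dataclass
class DiscordantRegion:
    """A discordant-pair enrichment interval — a breakpoint-graph node."""

    interval: GenomicInterval
    junction_side: str  # 'left' or 'right'
    supporting_read_ids: frozenset
    host_consecutive: Optional[ConsecutiveRegion] = None
    # filled in by the breakpoint estimator
    origin: Optional[int] = None
    breakpoint: Optional[int] = None
    ci: Optional[tuple[int, int]] = None
    estimate: Optional[object] = None

    def __post_init__(self) -> None:
        if self.junction_side not in ("left", "right"):
            raise ValueError(f"bad junction_side: {self.junction_side}")
        if not self.supporting_read_ids:
            raise ValueError("supporting_read_ids must be non-empty")


def _pileup_arrays(
    starts: np.ndarray, ends: np.ndarray, length: int, dtype=np.int32
) -> np.ndarray:
    diff = np.zeros(length + 1, dtype=dtype)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1], dtype=dtype)


def pileup(
    reads: "ReadTable | Iterable[AlignedRead]",
    contig_lengths: dict[str, int],
    mask: Optional[np.ndarray] = None,
) -> dict[str, DepthTrack]:
    """Per-base depth of read alignment spans, one track per contig."""
    if isinstance(reads, ReadTable):
        table = reads if mask is None else reads.select(mask)
        tracks = {}
        for tid, contig in enumerate(table.contigs):
            length = contig_lengths[contig]
            sel = table.tid == tid
            starts, ends = table.start[sel], table.end[sel]
            if len(ends) and int(ends.max(initial=0)) > length:
                bad = int(np.argmax(ends))
                raise ValueError(
                    f"read beyond contig {contig} length {length}: rid {table.rid[sel][bad]}"
                )
            tracks[contig] = DepthTrack(contig, _pileup_arrays(starts, ends, length))
        return tracks
    per_contig: dict[str, list[tuple[int, int, str]]] = {c: [] for c in contig_lengths}
    for r in reads:
        per_contig.setdefault(r.contig, []).append((r.start, r.end, r.read_id))
    tracks = {}
    for contig, length in contig_lengths.items():
        ivs = per_contig.get(contig, [])
        for s, e, rid in ivs:
            if e > length:
                raise ValueError(f"read {rid} beyond contig {contig} length {length}")
        starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
        tracks[contig] = DepthTrack(contig, _pileup_arrays(starts, ends, length))
    return tracks


def genome_lambda(
    tracks: dict[str, DepthTrack],
    blacklist: Optional[IntervalSet] = None,
    exclude: Sequence[ConsecutiveRegion] = (),
) -> float:
    """Mean depth over the effective genome.

    The effective length excludes blacklist intervals and, optionally, an
    initial set of called regions (so enriched mass does not inflate the
    background estimate on small genomes).
    """
    total_bases = 0.0
    total_len = 0
    excl_by_contig: dict[str, list[ConsecutiveRegion]] = {}
    for reg in exclude:
        excl_by_contig.setdefault(reg.interval.contig, []).append(reg)
    for contig, track in tracks.items():
        values = track.values
        keep = np.ones(len(values), dtype=bool)
        if blacklist is not None and blacklist:
            s_arr = blacklist._starts.get(contig)
            if s_arr is not None:
                for s, e in zip(s_arr, blacklist._ends[contig]):
                    keep[s:e] = False
        for reg in excl_by_contig.get(contig, ()):
            keep[reg.interval.start : reg.interval.end] = False
        total_bases += float(values[keep].sum(dtype=np.float64))
        total_len += int(keep.sum())
    if total_len == 0:
        raise ValueError("no bases left to estimate background depth")
    return total_bases / total_len


def _significant_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


def _merge_runs(runs: list[tuple[int, int]], merge_dist: int) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(runs):
        if merged and s - merged[-1][1] < merge_dist:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def call_consecutive_regions(
    tracks: "dict[str, DepthTrack] | DepthTrack",
    lam: float,
    p_cut: float = DEFAULT_P_CUT,
    merge_dist: int = DEFAULT_MERGE_DIST,
    min_len: int = DEFAULT_MIN_PEAK_LEN,
) -> list[ConsecutiveRegion]:
    """Call significantly enriched depth regions against Poisson(lam).

    A base is significant when P(X >= depth) < ``p_cut``.  Maximal significant
    runs shorter than ``min_len`` are dropped, then runs separated by less
    than ``merge_dist`` (strict) are merged.  Mean depth and fold enrichment
    are computed over the merged interval.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if isinstance(tracks, DepthTrack):
        tracks = {tracks.contig: tracks}
    cutoff = poisson_sf_threshold(lam, p_cut)
    regions: list[ConsecutiveRegion] = []
    for contig in tracks:
        values = tracks[contig].values
        runs = _significant_runs(values > cutoff)
        runs = [(s, e) for s, e in runs if e - s >= min_len]
        for s, e in _merge_runs(runs, merge_dist):
            mean_depth = float(values[s:e].mean(dtype=np.float64))
            regions.append(
                ConsecutiveRegion(
                    GenomicInterval(contig, s, e), mean_depth, mean_depth / lam
                )
            )
    regions.sort(key=lambda r: (r.interval.contig, r.interval.start))
    return regions


def _region_support(
    table: ReadTable,
    disc_mask: np.ndarray,
    tid: int,
    start: int,
    end: int,
    max_span: int = 5000,
) -> tuple[np.ndarray, np.ndarray]:
    """(rids, reverse) of discordant reads overlapping [start, end) on tid."""
    sel = (table.tid == tid) & disc_mask
    starts = table.start[sel]
    ends = table.end[sel]
    hit = (starts < end) & (ends > start) & (starts > start - max_span)
    return table.rid[sel][hit], table.reverse[sel][hit]


def call_discordant_regions(
    disc_tracks: dict[str, DepthTrack],
    total_tracks: dict[str, DepthTrack],
    reads: Optional[ReadTable] = None,
    disc_mask: Optional[np.ndarray] = None,
    score_cut: float = DEFAULT_SCORE_CUT,
    max_gap: int = DEFAULT_MAX_GAP,
    lam_ratio: Optional[float] = None,
    count_mode: bool = False,
    exclude: Sequence[ConsecutiveRegion] = (),
    lam_floor: float = 1e-9,
) -> list[DiscordantRegion]:
    """Call discordant-pair enrichment regions from the ratio Poisson test.

    Per base, r = discordant depth / total depth (0 where total is 0); the
    genome-wide mean of r over covered bases is the Poisson rate, and a base
    is significant when -log10 P(X >= r) >= ``score_cut``.  Significant runs
    separated by at most ``max_gap`` bases are stitched into one region.

    ``count_mode`` switches to the count-based alternative: the discordant
    depth itself is tested against its own genome-wide mean.

    Junction side is the majority strand vote of supporting discordant reads
    (forward -> right, reverse -> left); an exact tie emits one node per side.

    When ``exclude`` regions are given, the rate is estimated over the bases
    outside them, so enriched mass does not inflate the background rate on
    small genomes (negligible at full-genome scale, where enriched regions
    are a vanishing fraction of covered bases).
    """
    covered = 0
    covered_any = 0
    ratio_sum = 0.0
    ratios: dict[str, np.ndarray] = {}
    excl_by_contig: dict[str, list] = {}
    for reg in exclude:
        excl_by_contig.setdefault(reg.interval.contig, []).append(reg.interval)
    for contig, total in total_tracks.items():
        disc = disc_tracks[contig].values.astype(np.float64)
        tot = total.values
        if count_mode:
            r = disc
            keep = np.ones(len(disc), dtype=bool)
        else:
            nz = tot > 0
            r = np.zeros(len(tot), dtype=np.float64)
            r[nz] = disc[nz] / tot[nz]
            keep = nz
        bg = keep.copy()
        for iv in excl_by_contig.get(contig, ()):
            bg[iv.start : iv.end] = False
        ratio_sum += float(r[bg].sum())
        covered += int(bg.sum())
        covered_any += int(keep.sum())
        ratios[contig] = r
    if covered_any == 0 and lam_ratio is None:
        raise ValueError("total track has no coverage")
    if lam_ratio is not None:
        lam = lam_ratio
    elif covered > 0:
        lam = ratio_sum / covered
    else:
        lam = lam_floor
    lam = max(lam, lam_floor)
    p_threshold = 10.0 ** (-score_cut)
    cutoff = poisson_sf_threshold(lam, p_threshold)
    regions: list[DiscordantRegion] = []
    for contig in sorted(ratios):
        # score >= cut  <=>  sf <= 10^-cut  <=>  r >= cutoff crossing point
        runs = _merge_runs(_significant_runs(ratios[contig] >= cutoff), max_gap + 1)
        if not runs:
            continue
        tid = (
            reads.contigs.index(contig)
            if reads is not None and contig in reads.contigs
            else -1
        )
        for s, e in runs:
            if reads is not None and tid >= 0 and disc_mask is not None:
                rids, reverse = _region_support(reads, disc_mask, tid, s, e)
            else:
                rids, reverse = np.array([], dtype=np.int64), np.array([], dtype=bool)
            if len(rids) == 0:
                # no attributable reads (track-only invocation): skip silently
                continue
            n_rev = int(reverse.sum())
            n_fwd = len(reverse) - n_rev
            ids = frozenset(rids.tolist())
            iv = GenomicInterval(contig, s, e)
            if n_fwd > n_rev:
                regions.append(DiscordantRegion(iv, "right", ids))
            elif n_rev > n_fwd:
                regions.append(DiscordantRegion(iv, "left", ids))
            else:
                regions.append(DiscordantRegion(iv, "left", ids))
                regions.append(DiscordantRegion(iv, "right", ids))
    return regions


def attach_to_consecutive(
    disc: Sequence[DiscordantRegion],
    consec: Sequence[ConsecutiveRegion],
) -> list[DiscordantRegion]:
    """Keep discordant regions overlapping a consecutive region; set hosts.

    Any overlap (>= 1 bp) qualifies; ties on overlap size go to the larger
    overlap first, then to the earlier region.
    """
    kept = []
    for d in disc:
        best = None
        best_ov = 0
        for c in consec:
            ov = d.interval.overlap_len(c.interval)
            if ov > best_ov:
                best, best_ov = c, ov
        if best is not None:
            d.host_consecutive = best
            kept.append(d)
    return kept


def write_bedgraph(tracks: dict[str, DepthTrack], path: str) -> None:
    """Run-length-compressed bedGraph export of a depth track set."""
    with open(path, "w") as fh:
        for contig in sorted(tracks):
            values = tracks[contig].values
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            bounds = np.concatenate(([0], change, [len(values)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = values[s]
                if v != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


def write_regions_bed(regions: Sequence[object], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for i, reg in enumerate(regions):
            iv = reg.interval
            side = getattr(reg, "junction_side", ".")
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\tregion{i}_{side}\n")
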