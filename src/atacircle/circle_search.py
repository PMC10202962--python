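"""Alternating-edge circle enumeration and candidate filtering.

A candidate ecDNA is a closed walk in the breakpoint multigraph that visits
each node at most once and strictly alternates consecutive and discordant
edges, so every circle pairs one retained segment with one junction per
step.  The search is a depth-first traversal that always expands larger,
deeper segments first; duplicates under rotation and reflection are removed
through a canonical structure key, and the output is capped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .alignment_io import GenomicInterval, IntervalSet
from .breakpoint_graph import CONSECUTIVE, DISCORDANT

__all__ = [
    "OrientedSegment",
    "Junction",
    "CircleCandidate",
    "find_circles",
    "canonical_structure",
    "apply_filters",
    "write_candidates_bed",
    "write_candidates_json",
    "load_candidates_json",
]


@dataclass(frozen=True)
class OrientedSegment:
    interval: GenomicInterval
    strand: str
    mean_depth: float = float("nan")
    fold_enrichment: float = float("nan")

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand: {self.strand}")

    @property
    def length(self) -> int:
        return self.interval.length

    def key(self) -> tuple:
        return (self.interval.contig, self.interval.start, self.interval.end, self.strand)


@dataclass
class Junction:
    """Support and breakpoint uncertainty for one segment-to-segment join."""

    support: int
    read_ids: frozenset = frozenset()
    ci_a: Optional[tuple[int, int]] = None  # exit side of segment i
    ci_b: Optional[tuple[int, int]] = None  # entry side of segment i+1


@dataclass
class CircleCandidate:
    circle_id: str
    segments: list[OrientedSegment]
    junctions: list[Junction]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a circle needs at least one segment")
        if len(self.junctions) != len(self.segments):
            raise ValueError("#junctions must equal #segments")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def min_fold_enrichment(self) -> float:
        return min(s.fold_enrichment for s in self.segments)

    @property
    def min_support(self) -> int:
        return min(j.support for j in self.junctions)


def canonical_structure(segments: "CircleCandidate | Sequence[tuple]") -> tuple:
    """Rotation- and reflection-invariant key of a cyclic oriented structure.

    The key is the lexicographic minimum over all rotations of the segment
    tuple sequence in both traversal directions (reversal flips every
    strand).
    """
    if isinstance(segments, CircleCandidate):
        seq = [s.key() for s in segments.segments]
    else:
        seq = [tuple(s) for s in segments]
    k = len(seq)
    flipped = [
        (c, s, e, "-" if strand == "+" else "+") for c, s, e, strand in reversed(seq)
    ]
    best = None
    for variant in (seq, flipped):
        for r in range(k):
            rot = tuple(variant[r:] + variant[:r])
            if best is None or rot < best:
                best = rot
    return best


def _edge_priority(data: dict) -> tuple:
    seg = data["segment"]
    return (-seg.length, -data.get("mean_depth", 0.0))


def find_circles(
    graph: nx.MultiGraph,
    max_outputs: int = 1000,
    max_steps: int = 2_000_000,
) -> list[CircleCandidate]:
    """Enumerate alternation-valid simple cycles in priority order.

    Every start node is tried (priority order: its best incident segment,
    largest and deepest first); the first edge out is always consecutive, so
    a closed walk ends on a discordant edge back to the start.  Each branch
    expands consecutive edges in priority order.  Structures already seen
    (up to rotation/reflection) are skipped; at most ``max_outputs`` survive.
    ``max_steps`` bounds total expansions as a safety valve on pathological
    graphs.
    """
    consec: dict[int, list[tuple[int, int, dict]]] = {}
    disc: dict[int, list[tuple[int, int, dict]]] = {}
    for u, v, key, data in graph.edges(keys=True, data=True):
        target = consec if data["etype"] == CONSECUTIVE else disc
        target.setdefault(u, []).append((v, key, data))
        target.setdefault(v, []).append((u, key, data))
    for node in consec:
        consec[node].sort(key=lambda t: (_edge_priority(t[2]), t[0], t[1]))
    for node in disc:
        disc[node].sort(key=lambda t: (-len(t[2]["support"]), t[0], t[1]))

    def start_priority(node: int) -> tuple:
        edges = consec.get(node, [])
        best = min((_edge_priority(d) for _, _, d in edges), default=(0, 0))
        return (best, node)

    results: list[CircleCandidate] = []
    seen: set[tuple] = set()
    steps = 0

    def build(path_nodes: list[int], path_edges: list[tuple[str, dict, int, int]]):
        segments: list[OrientedSegment] = []
        junctions: list[Junction] = []
        for etype, data, u, v in path_edges:
            if etype == CONSECUTIVE:
                left_node = u if graph.nodes[u]["region"].junction_side == "left" else v
                strand = "+" if u == left_node else "-"
                segments.append(
                    OrientedSegment(
                        data["segment"],
                        strand,
                        data.get("mean_depth", float("nan")),
                        data.get("fold_enrichment", float("nan")),
                    )
                )
            else:
                ra = graph.nodes[u]["region"]
                rb = graph.nodes[v]["region"]
                junctions.append(
                    Junction(
                        support=len(data["support"]),
                        read_ids=data["support"],
                        ci_a=ra.ci,
                        ci_b=rb.ci,
                    )
                )
        # path order already pairs junctions[i] with segments[i] -> segments[i+1]
        return CircleCandidate(f"circle{len(results)}", segments, junctions)

    def dfs(start: int, node: int, visited: set[int],
            path_nodes: list[int], path_edges: list) -> bool:
        nonlocal steps
        last_type = path_edges[-1][0] if path_edges else None
        if last_type == CONSECUTIVE:
            # may close via a discordant edge back to start
            for v, key, data in disc.get(node, []):
                if v == start and len(path_edges) >= 1:
                    steps += 1
                    cand = build(path_nodes, path_edges + [(DISCORDANT, data, node, v)])
                    key_c = canonical_structure(cand)
                    if key_c not in seen:
                        seen.add(key_c)
                        results.append(cand)
                        if len(results) >= max_outputs:
                            return True
            nxt = disc.get(node, [])
            nxt_type = DISCORDANT
        else:
            nxt = consec.get(node, [])
            nxt_type = CONSECUTIVE
        for v, key, data in nxt:
            if v in visited or v == start:
                continue
            steps += 1
            if steps > max_steps:
                return True
            visited.add(v)
            stop = dfs(start, v, visited, path_nodes + [v],
                       path_edges + [(nxt_type, data, node, v)])
            visited.remove(v)
            if stop:
                return True
        return False

    for start in sorted(graph.nodes, key=start_priority):
        if dfs(start, start, {start}, [start], []):
            break
    for i, cand in enumerate(results):
        cand.circle_id = f"circle{i}"
    return results[:max_outputs]


def apply_filters(
    cands: Iterable[CircleCandidate],
    fold_min: float = 10.0,
    support_min: int = 3,
    repeats: Optional[IntervalSet] = None,
    max_repeat_frac: float = 0.05,
) -> list[CircleCandidate]:
    """The candidate-level report filters.

    Keeps circles whose weakest segment's fold enrichment strictly exceeds
    ``fold_min``, whose every junction is supported by at least
    ``support_min`` read IDs, and (when a repeat mask is given) whose
    repeat-overlapped fraction of total length stays below
    ``max_repeat_frac``.
    """
    kept = []
    for cand in cands:
        if not cand.min_fold_enrichment > fold_min:
            continue
        if cand.min_support < support_min:
            continue
        if repeats is not None and repeats:
            overlap = sum(
                repeats.overlap_bases(s.interval.contig, s.interval.start, s.interval.end)
                for s in cand.segments
            )
            if not overlap / cand.total_length < max_repeat_frac:
                continue
        kept.append(cand)
    return kept


def write_candidates_bed(cands: Sequence[CircleCandidate], path: str) -> None:
    """One row per segment in the output BED dialect (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand"
            "\tci_start_low\tci_start_high\tci_end_low\tci_end_high\n"
        )
        for cand in cands:
            k = len(cand.segments)
            for i, seg in enumerate(cand.segments):
                junc_in = cand.junctions[(i - 1) % k]
                junc_out = cand.junctions[i % k]
                score = min(junc_out.support, 1000)
                ci_start = junc_in.ci_b or (seg.interval.start, seg.interval.start)
                ci_end = junc_out.ci_a or (seg.interval.end, seg.interval.end)
                if seg.strand == "-":
                    ci_start, ci_end = ci_end, ci_start
                fh.write(
                    f"{seg.interval.contig}\t{seg.interval.start}\t{seg.interval.end}"
                    f"\t{cand.circle_id}_{i + 1}_of_{k}\t{score}\t{seg.strand}"
                    f"\t{ci_start[0]}\t{ci_start[1]}\t{ci_end[0]}\t{ci_end[1]}\n"
                )


def _cand_to_dict(cand: CircleCandidate) -> dict:
    return {
        "circle_id": cand.circle_id,
        "total_length": cand.total_length,
        "segments": [
            {
                "contig": s.interval.contig,
                "start": s.interval.start,
                "end": s.interval.end,
                "strand": s.strand,
                "mean_depth": None if s.mean_depth != s.mean_depth else s.mean_depth,
                "fold_enrichment": (
                    None if s.fold_enrichment != s.fold_enrichment else s.fold_enrichment
                ),
            }
            for s in cand.segments
        ],
        "junctions": [
            {"support": j.support, "ci_a": j.ci_a, "ci_b": j.ci_b}
            for j in cand.junctions
        ],
    }


def write_candidates_json(cands: Sequence[CircleCandidate], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([_cand_to_dict(c) for c in cands], fh, indent=1)
        fh.write("\n")


def load_candidates_json(path: str) -> list[CircleCandidate]:
    with open(path) as fh:
        raw = json.load(fh)
    cands = []
    for item in raw:
        segments = [
            OrientedSegment(
                GenomicInterval(s["contig"], s["start"], s["end"]),
                s["strand"],
                s["mean_depth"] if s["mean_depth"] is not None else float("nan"),
                s["fold_enrichment"] if s["fold_enrichment"] is not None else float("nan"),
            )
            for s in item["segments"]
        ]
        junctions = [
            Junction(
                support=j["support"],
                ci_a=tuple(j["ci_a"]) if j["ci_a"] else None,
                ci_b=tuple(j["ci_b"]) if j["ci_b"] else None,
            )
            for j in item["junctions"]
        ]
        cands.append(CircleCandidate(item["circle_id"], segments, junctions))
    return cands
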