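"""The two-edge-type breakpoint multigraph.

Nodes are discordant-pair enrichment regions (indexed in coordinate order);
edges are either *discordant* (two regions share enough same-orientation read
pairs — a junction) or *consecutive* (two opposite-side regions within one
consecutive enrichment region — the retained DNA segment between them).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .alignment_io import GenomicInterval, ReadTable
from .enrichment import (
    ConsecutiveRegion,
    DepthTrack,
    DiscordantRegion,
    poisson_sf,
)

__all__ = [
    "DISCORDANT",
    "CONSECUTIVE",
    "min_support_default",
    "build_graph",
    "add_discordant_edges",
    "add_consecutive_edges",
    "export_edge_list",
]

logger = logging.getLogger(__name__)

DISCORDANT = "discordant"
CONSECUTIVE = "consecutive"


def min_support_default(lam_disc: float, alpha: float = 0.05, floor: int = 3) -> int:
    """Default minimum read-pair support for a discordant edge.

    The Poisson inverse survival at ``alpha`` (smallest k with
    P(X >= k) < alpha under Poisson(lam_disc)), floored at ``floor`` so the
    default never falls below the downstream junction-support filter.
    """
    if lam_disc <= 0:
        raise ValueError("lam_disc must be positive")
    k = 0
    while poisson_sf(k, lam_disc) >= alpha:
        k += 1
    return max(floor, k)


def build_graph(regions: Sequence[DiscordantRegion]) -> nx.MultiGraph:
    """Multigraph with one node per discordant region, coordinate-ordered ids."""
    ordered = sorted(
        regions,
        key=lambda r: (r.interval.contig, r.interval.start, r.junction_side),
    )
    graph = nx.MultiGraph()
    for i, region in enumerate(ordered):
        graph.add_node(i, region=region)
    return graph


def _pair_membership(
    graph: nx.MultiGraph,
    table: ReadTable,
    disc_mask: np.ndarray,
) -> dict[int, list[tuple[int, bool]]]:
    """rid -> [(node, reverse strand), ...] over discordant reads in regions."""
    members: dict[int, list[tuple[int, bool]]] = {}
    sel = disc_mask
    rids = table.rid[sel]
    tids = table.tid[sel]
    starts = table.start[sel]
    ends = table.end[sel]
    reverse = table.reverse[sel]
    contig_tid = {c: i for i, c in enumerate(table.contigs)}
    for node, data in graph.nodes(data=True):
        region = data["region"]
        tid = contig_tid.get(region.interval.contig)
        if tid is None:
            continue
        hit = (
            (tids == tid)
            & (starts < region.interval.end)
            & (ends > region.interval.start)
        )
        for rid, rev in zip(rids[hit].tolist(), reverse[hit].tolist()):
            members.setdefault(rid, []).append((node, rev))
    return members


def add_discordant_edges(
    graph: nx.MultiGraph,
    table: ReadTable,
    disc_mask: np.ndarray,
    min_support: int = 3,
) -> nx.MultiGraph:
    """Add one discordant edge per node pair with enough consistent support.

    Two nodes are linked when at least ``min_support`` read IDs place one
    mate in each node with a consistent orientation signature (strand at
    node A, strand at node B).  Only the majority signature's reads count as
    support.  A read ID touching more than two nodes is ambiguous and is
    discarded.  The winning signature is recorded on both nodes as their
    extension direction.
    """
    members = _pair_membership(graph, table, disc_mask)
    pair_sig: dict[tuple[int, int], dict[tuple[bool, bool], set[int]]] = {}
    for rid, placements in members.items():
        nodes = {n for n, _ in placements}
        if len(nodes) != 2 or len(placements) > 2:
            continue  # single-node or ambiguous (>2 regions) read id
        (na, ra), (nb, rb) = placements
        if na > nb:
            na, nb, ra, rb = nb, na, rb, ra
        pair_sig.setdefault((na, nb), {}).setdefault((ra, rb), set()).add(rid)
    for (na, nb), signatures in sorted(pair_sig.items()):
        sig, rids = max(
            signatures.items(), key=lambda kv: (len(kv[1]), kv[0])
        )
        if len(rids) < min_support:
            continue
        graph.add_edge(
            na, nb, etype=DISCORDANT, support=frozenset(rids), signature=sig
        )
        graph.nodes[na]["extension"] = "left" if sig[0] else "right"
        graph.nodes[nb]["extension"] = "left" if sig[1] else "right"
    return graph


def add_consecutive_edges(
    graph: nx.MultiGraph,
    depth_tracks: Optional[dict[str, DepthTrack]] = None,
    lam: Optional[float] = None,
) -> nx.MultiGraph:
    """Link properly oriented node pairs within each consecutive region.

    "Properly oriented" means the junction sides face each other: a
    left-side node upstream of a right-side node, so the spanned segment
    [left.breakpoint, right.breakpoint) is the DNA retained in the circle.
    All orderable opposite-side pairs receive an edge; the circle search, not
    graph construction, arbitrates between alternatives.
    """
    by_host: dict[int, list[int]] = {}
    hosts: dict[int, ConsecutiveRegion] = {}
    for node, data in graph.nodes(data=True):
        host = data["region"].host_consecutive
        if host is None:
            continue
        by_host.setdefault(id(host), []).append(node)
        hosts[id(host)] = host
    for host_id, nodes in sorted(by_host.items(), key=lambda kv: kv[1]):
        host = hosts[host_id]
        lefts = [n for n in nodes if graph.nodes[n]["region"].junction_side == "left"]
        rights = [n for n in nodes if graph.nodes[n]["region"].junction_side == "right"]
        for u in sorted(lefts):
            for v in sorted(rights):
                ru = graph.nodes[u]["region"]
                rv = graph.nodes[v]["region"]
                bp_u = ru.breakpoint if ru.breakpoint is not None else ru.interval.start
                bp_v = rv.breakpoint if rv.breakpoint is not None else rv.interval.end
                if ru.interval.start > rv.interval.start or bp_u >= bp_v:
                    continue
                segment = GenomicInterval(ru.interval.contig, bp_u, bp_v)
                if depth_tracks is not None and segment.contig in depth_tracks:
                    mean_depth = depth_tracks[segment.contig].mean_over(
                        segment.start, segment.end
                    )
                else:
                    mean_depth = host.mean_depth
                fold = mean_depth / lam if lam else host.fold_enrichment
                graph.add_edge(
                    u,
                    v,
                    etype=CONSECUTIVE,
                    segment=segment,
                    mean_depth=mean_depth,
                    fold_enrichment=fold,
                )
    return graph


def export_edge_list(graph: nx.MultiGraph, path: str) -> None:
    """Plain-text debug dump: node BED coordinates plus typed edges."""
    with open(path, "w") as fh:
        fh.write("#node\tcontig\tstart\tend\tside\tbreakpoint\n")
        for node, data in sorted(graph.nodes(data=True)):
            r = data["region"]
            fh.write(
                f"{node}\t{r.interval.contig}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.junction_side}\t{r.breakpoint if r.breakpoint is not None else '.'}\n"
            )
        fh.write("#edge\tu\tv\ttype\tsupport_or_segment\n")
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1])):
            if data["etype"] == DISCORDANT:
                detail = str(len(data["support"]))
            else:
                detail = str(data["segment"])
            fh.write(f"edge\t{u}\t{v}\t{data['etype']}\t{detail}\n")
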