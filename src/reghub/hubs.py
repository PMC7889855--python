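"""Regulatory-hub discovery over the loop anchor graph.

A regulatory hub is the set of genomic regions reachable from a disease-risk
LD block through chains of CTCF-mediated loops: start at the block, take every
region it loops to, then every region those loop to, and so on until closure.
That traversal is exactly a connected component of the *anchor graph*, whose
nodes are the merged loop anchors and whose edges are the filtered loops.

An LD block that overlaps no loop anchor is *inactive* (no CTCF contact in
this cell type) and seeds no hub.  LD blocks falling in the same component
share one hub with multiple seed blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx

from .consensus import ConsensusPeakSet
from .intervals import (
    Gene,
    GenomicInterval,
    LDBlock,
    Loop,
    find_overlapping,
    merge_intervals,
    overlaps,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchorGraph:
    """Merged loop anchors (nodes) connected by loops (weighted edges)."""

    nodes: tuple[GenomicInterval, ...]
    edges: dict  # (i, j) with i <= j -> number of supporting loops

    def n_components(self) -> int:
        return nx.number_connected_components(self._nx())

    def _nx(self) -> "nx.Graph":
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(self.edges.keys())
        return g


@dataclass(frozen=True)
class Hub:
    """A connected component of the anchor graph seeded by >= 1 LD block."""

    hub_id: str
    seed_blocks: tuple[LDBlock, ...]
    anchor_regions: tuple[GenomicInterval, ...]
    member_genes: tuple[Gene, ...] = field(default_factory=tuple)
    member_peaks: tuple[tuple[str, GenomicInterval], ...] = field(default_factory=tuple)

    @property
    def n_genes(self) -> int:
        return len(self.member_genes)

    @property
    def n_peaks(self) -> int:
        return len(self.member_peaks)


def build_anchor_graph(loops: list[Loop]) -> AnchorGraph:
    """Merge all loop anchors into disjoint nodes and wire loops as edges.

    Each loop contributes one edge between the nodes containing its anchors;
    a loop whose two anchors merge into the same node becomes a self-edge.
    Edge weight counts supporting loops.
    """
    anchors = [a for loop in loops for a in (loop.anchor1, loop.anchor2)]
    nodes = tuple(merge_intervals(anchors))
    edges: dict[tuple[int, int], int] = {}
    for loop in loops:
        i = _containing_node(loop.anchor1, nodes)
        j = _containing_node(loop.anchor2, nodes)
        key = (min(i, j), max(i, j))
        edges[key] = edges.get(key, 0) + 1
    n_self = sum(1 for i, j in edges if i == j)
    n_trans = sum(
        1 for i, j in edges if nodes[i].chrom != nodes[j].chrom
    )
    if n_trans:
        logger.warning("anchor graph has %d inter-chromosomal edges", n_trans)
    logger.info(
        "anchor graph: %d nodes, %d edges (%d self-edges)", len(nodes), len(edges), n_self
    )
    return AnchorGraph(nodes=nodes, edges=edges)


def _containing_node(anchor: GenomicInterval, nodes: tuple[GenomicInterval, ...]) -> int:
    hits = find_overlapping(anchor, nodes)
    # anchors built the merged nodes, so exactly one node contains each anchor
    assert len(hits) == 1, f"anchor {anchor} maps to {len(hits)} nodes"
    return hits[0]


def find_hubs(
    graph: AnchorGraph,
    ld_blocks: list[LDBlock],
    strict_containment: bool = False,
) -> list[Hub]:
    """Connected components of the anchor graph seeded by overlapping LD blocks.

    Returns one hub per component containing >= 1 LD-block-overlapping node,
    ordered by the leftmost anchor coordinate.  Blocks overlapping no node are
    inactive and reported via :func:`inactive_blocks`.  With
    ``strict_containment`` a block seeds a component only when it fully
    contains an anchor node (any overlap by default).
    """
    components = _components(graph)
    node_to_comp: dict[int, int] = {}
    for ci, comp in enumerate(components):
        for n in comp:
            node_to_comp[n] = ci

    seeds_by_comp: dict[int, list[LDBlock]] = {}
    for block in sorted(ld_blocks, key=lambda b: (b.interval.chrom, b.interval.start)):
        hits = find_overlapping(block.interval, graph.nodes)
        if strict_containment:
            hits = [
                i
                for i in hits
                if block.interval.start <= graph.nodes[i].start
                and graph.nodes[i].end <= block.interval.end
            ]
        touched = {node_to_comp[i] for i in hits}
        for ci in sorted(touched):
            seeds_by_comp.setdefault(ci, []).append(block)

    hubs = []
    for ci in sorted(
        seeds_by_comp,
        key=lambda ci: min(
            (graph.nodes[n].chrom, graph.nodes[n].start) for n in components[ci]
        ),
    ):
        regions = tuple(
            sorted(
                (graph.nodes[n] for n in components[ci]),
                key=lambda iv: (iv.chrom, iv.start, iv.end),
            )
        )
        hubs.append(
            Hub(
                hub_id=f"hub_{len(hubs)}",
                seed_blocks=tuple(seeds_by_comp[ci]),
                anchor_regions=regions,
            )
        )
    logger.info(
        "find_hubs: %d hubs from %d LD blocks (%d inactive)",
        len(hubs), len(ld_blocks), len(inactive_blocks(graph, ld_blocks)),
    )
    return hubs


def inactive_blocks(graph: AnchorGraph, ld_blocks: list[LDBlock]) -> list[LDBlock]:
    """LD blocks overlapping no loop anchor: inactive in this cell type."""
    return [
        b for b in ld_blocks if not find_overlapping(b.interval, graph.nodes)
    ]


def _components(graph: AnchorGraph) -> list[list[int]]:
    return [sorted(c) for c in nx.connected_components(graph._nx())]


def assign_members(
    hub: Hub,
    genes: list[Gene],
    atac_consensus: ConsensusPeakSet,
    promoter_pad: int = 2000,
    anchor_pad: int = 0,
) -> Hub:
    """Attach member genes and ATAC peaks to a hub.

    A gene is a member when its promoter window (TSS +/- ``promoter_pad``)
    overlaps any anchor region (padded by ``anchor_pad``) or any seed LD
    block — elements inside the risk block itself must be scoreable even if
    they sit between anchors.  Likewise an ATAC consensus region is a member
    peak when it overlaps an anchor region or a seed block.  Members are
    ordered by coordinate; peak ids index the full sorted consensus list.
    """
    targets = [iv.padded(anchor_pad) for iv in hub.anchor_regions] + [
        b.interval for b in hub.seed_blocks
    ]

    member_genes = tuple(
        sorted(
            (
                g
                for g in genes
                if any(overlaps(g.promoter(promoter_pad), t) for t in targets)
            ),
            key=lambda g: (g.span.chrom, g.span.start, g.gene_id),
        )
    )

    member_peaks = tuple(
        (f"atac_peak_{k}", iv)
        for k, iv in enumerate(atac_consensus.intervals)
        if any(overlaps(iv, t) for t in targets)
    )

    if not member_genes and not member_peaks:
        logger.warning("hub %s has no member genes or peaks", hub.hub_id)
    return replace(hub, member_genes=member_genes, member_peaks=member_peaks)
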