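"""Anchor graph and hub discovery vs a brute-force transitive-closure oracle."""

import numpy as np
import pytest

from reghub.consensus import ConsensusPeakSet
from reghub.hubs import (
    assign_members,
    build_anchor_graph,
    find_hubs,
    inactive_blocks,
)
from reghub.intervals import Gene, GenomicInterval, LDBlock, Loop, overlaps

from conftest import base_set, oracle_segment_count


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def loop(a, b, support=5):
    return Loop(iv(*a), iv(*b), read_support=support)


class TestAnchorGraph:
    def test_shared_exact_anchor_three_nodes_two_edges(self):
        loops = [loop((0, 100), (1000, 1100)), loop((1000, 1100), (5000, 5100))]
        g = build_anchor_graph(loops)
        assert len(g.nodes) == 3
        assert set(g.edges) == {(0, 1), (1, 2)}

    def test_overlapping_anchors_merge_into_one_node(self):
        loops = [loop((0, 100), (1000, 1100)), loop((1050, 1200), (5000, 5100))]
        g = build_anchor_graph(loops)
        assert len(g.nodes) == 3
        assert iv(1000, 1200) in g.nodes

    def test_self_edge_when_both_anchors_merge(self):
        loops = [loop((0, 100), (50, 150))]
        g = build_anchor_graph(loops)
        assert len(g.nodes) == 1
        assert set(g.edges) == {(0, 0)}

    def test_edge_weight_counts_supporting_loops(self):
        loops = [loop((0, 100), (1000, 1100)), loop((10, 90), (1010, 1090))]
        g = build_anchor_graph(loops)
        assert g.edges[(0, 1)] == 2

    def test_node_count_matches_per_base_union_segments(self, rng):
        for _ in range(30):
            loops = _random_loops(rng, n=30)
            g = build_anchor_graph(loops)
            anchors = [a for lo in loops for a in (lo.anchor1, lo.anchor2)]
            assert len(g.nodes) == oracle_segment_count(anchors)
            assert base_set(g.nodes) == base_set(anchors)


def _random_loops(rng, n, span=2000, width=60):
    loops = []
    for _ in range(n):
        chrom = "chr1" if rng.random() < 0.8 else "chr2"
        s1 = int(rng.integers(0, span))
        s2 = int(rng.integers(0, span))
        loops.append(
            Loop(
                GenomicInterval(chrom, s1, s1 + 1 + int(rng.integers(width))),
                GenomicInterval(chrom, s2, s2 + 1 + int(rng.integers(width))),
                read_support=int(rng.integers(2, 9)),
            )
        )
    return loops


def _random_blocks(rng, n, span=2000):
    out = []
    for k in range(n):
        s = int(rng.integers(0, span))
        out.append(
            LDBlock(GenomicInterval("chr1", s, s + 1 + int(rng.integers(150))), f"rs{k}")
        )
    return out


def _oracle_components(loops, ld_blocks):
    """Transitive closure over per-base overlap of anchors + loop links.

    Returns, per LD block, the frozenset of covered bases reachable from it
    (empty when the block touches no anchor).
    """
    anchors = [a for lo in loops for a in (lo.anchor1, lo.anchor2)]
    n = len(anchors)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and overlaps(anchors[i], anchors[j]):
                adj[i][j] = True
    for k, lo in enumerate(loops):
        adj[2 * k][2 * k + 1] = adj[2 * k + 1][2 * k] = True
    reach = {}
    for b in ld_blocks:
        frontier = {i for i in range(n) if overlaps(b.interval, anchors[i])}
        seen = set(frontier)
        while frontier:
            nxt = set()
            for i in frontier:
                for j in range(n):
                    if adj[i][j] and j not in seen:
                        nxt.add(j)
            seen |= nxt
            frontier = nxt
        reach[b.lead_snp] = frozenset().union(
            *[base_set([anchors[i]]) for i in seen] or [frozenset()]
        )
    return reach


class TestFindHubs:
    def test_chain_traversal(self):
        loops = [
            loop((0, 100), (1000, 1100)),       # A-B
            loop((1000, 1100), (5000, 5100)),   # B-C
            loop((9000, 9100), (12000, 12100)), # D-E, separate
        ]
        block = LDBlock(iv(50, 60), "rs1")
        (hub,) = find_hubs(build_anchor_graph(loops), [block])
        assert hub.anchor_regions == (iv(0, 100), iv(1000, 1100), iv(5000, 5100))
        assert hub.seed_blocks == (block,)

    def test_block_without_anchor_is_inactive(self):
        loops = [loop((0, 100), (1000, 1100))]
        graph = build_anchor_graph(loops)
        block = LDBlock(iv(50_000, 60_000), "rs_far")
        assert find_hubs(graph, [block]) == []
        assert inactive_blocks(graph, [block]) == [block]

    def test_blocks_sharing_component_merge_into_one_hub(self):
        loops = [loop((0, 100), (1000, 1100))]
        graph = build_anchor_graph(loops)
        b1 = LDBlock(iv(10, 20), "rs1")
        b2 = LDBlock(iv(1010, 1020), "rs2")
        (hub,) = find_hubs(graph, [b1, b2])
        assert {b.lead_snp for b in hub.seed_blocks} == {"rs1", "rs2"}

    def test_invariant_to_input_order(self, rng):
        loops = _random_loops(rng, 20)
        blocks = _random_blocks(rng, 5)
        graph = build_anchor_graph(loops)
        ref = find_hubs(graph, blocks)
        perm_loops = [loops[i] for i in rng.permutation(len(loops))]
        perm_blocks = [blocks[i] for i in rng.permutation(len(blocks))]
        alt = find_hubs(build_anchor_graph(perm_loops), perm_blocks)
        assert [h.anchor_regions for h in alt] == [h.anchor_regions for h in ref]
        assert [
            {b.lead_snp for b in h.seed_blocks} for h in alt
        ] == [{b.lead_snp for b in h.seed_blocks} for h in ref]

    def test_equals_transitive_closure_oracle_on_random_instances(self, rng):
        for _ in range(100):
            loops = _random_loops(rng, int(rng.integers(1, 51)))
            blocks = _random_blocks(rng, int(rng.integers(1, 11)))
            graph = build_anchor_graph(loops)
            hubs = find_hubs(graph, blocks)
            oracle = _oracle_components(loops, blocks)

            by_snp = {}
            for h in hubs:
                for b in h.seed_blocks:
                    # a block touching several components seeds several hubs
                    by_snp.setdefault(b.lead_snp, set()).update(
                        base_set(h.anchor_regions)
                    )
            for b in blocks:
                assert by_snp.get(b.lead_snp, set()) == set(oracle[b.lead_snp])

    def test_hubs_partition_reachable_nodes(self, rng):
        loops = _random_loops(rng, 40)
        blocks = _random_blocks(rng, 8)
        hubs = find_hubs(build_anchor_graph(loops), blocks)
        seen = set()
        for h in hubs:
            regions = set(h.anchor_regions)
            assert not (regions & seen)
            seen |= regions


class TestAssignMembers:
    def setup_method(self):
        loops = [loop((10_000, 12_000), (110_000, 112_000))]
        self.graph = build_anchor_graph(loops)
        self.block = LDBlock(iv(9_000, 13_000), "rs1")
        (self.hub,) = find_hubs(self.graph, [self.block])
        self.atac = ConsensusPeakSet(
            group_id="atac",
            n_samples=5,
            regions=(
                (iv(9_100, 9_500), 4),       # inside LD block only
                (iv(10_500, 10_900), 5),     # inside anchor 1
                (iv(500_000, 500_400), 5),   # far away
            ),
        )

    def test_gene_with_tss_in_anchor_is_member(self):
        g = Gene("hit", iv(111_000, 120_000), "+")
        hub = assign_members(self.hub, [g], self.atac)
        assert [m.gene_id for m in hub.member_genes] == ["hit"]

    def test_gene_10kb_away_with_2kb_promoter_is_not_member(self):
        g = Gene("miss", iv(122_001, 130_000), "+")
        hub = assign_members(self.hub, [g], self.atac, promoter_pad=2000)
        assert hub.member_genes == ()

    def test_peak_in_seed_block_but_not_anchor_is_member(self):
        hub = assign_members(self.hub, [], self.atac)
        assert [str(ivl) for _, ivl in hub.member_peaks] == [
            "chr1:9100-9500",
            "chr1:10500-10900",
        ]

    def test_peak_ids_index_full_consensus_list(self):
        hub = assign_members(self.hub, [], self.atac)
        assert [pid for pid, _ in hub.member_peaks] == ["atac_peak_0", "atac_peak_1"]
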