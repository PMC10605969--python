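"""Subgraph extraction, exports, colors, and the neighbor-variant scan."""

import pytest

from ccdbg import (
    PanGenomeText,
    build_graph,
    build_index,
    export_subgraph,
    extract_subgraph,
    neighbor_variant_scan,
    node_colors,
    node_substring,
)
from oracles import ExplicitGraph


class TestWorkedExample:
    def test_depth1_ball_around_node1(self, example_index, example_graph):
        sub = extract_subgraph(example_graph, example_index, {1}, 1)
        assert sub.node_ids == {0, 1, 2, 3, 4}
        assert sub.edges[(1, 0)] == 1 and sub.edges[(1, 4)] == 1

    def test_depth0_is_seed_only(self, example_index, example_graph):
        sub = extract_subgraph(example_graph, example_index, {0}, 0)
        assert sub.node_ids == {0} and not sub.edges

    def test_unknown_seed_rejected(self, example_index, example_graph):
        with pytest.raises(IndexError):
            extract_subgraph(example_graph, example_index, {99}, 1)

    def test_colors(self, example_index, example_graph):
        g, ix = example_graph, example_index
        assert node_colors(g, ix, 0) == {0, 1}
        assert node_colors(g, ix, 3) == {0}
        assert node_colors(g, ix, 2) == {1}

    def test_cyclic_edges_flag(self, example_index, example_graph):
        closed = extract_subgraph(example_graph, example_index, {5}, 1)
        opened = extract_subgraph(
            example_graph, example_index, {5}, 1, include_cyclic=True
        )
        assert (5, 3) not in closed.edges  # $CT -> CTA wrap edge hidden
        assert (5, 3) in opened.edges


class TestExports:
    def test_dot_node_count(self, example_index, example_graph):
        sub = extract_subgraph(example_graph, example_index, {1}, 1)
        doc = export_subgraph(sub, example_graph, example_index, "dot")
        assert sum(1 for ln in doc.splitlines() if "label=" in ln and "->" not in ln) == 5

    def test_gfa_single_node(self, example_index, example_graph):
        sub = extract_subgraph(example_graph, example_index, {0}, 0)
        doc = export_subgraph(sub, example_graph, example_index, "gfa1")
        s_lines = [ln for ln in doc.splitlines() if ln.startswith("S\t")]
        assert s_lines == ["S\t0\tGTC"]

    def test_empty_subgraph_header_only(self, example_index, example_graph):
        from ccdbg.subgraph import Subgraph

        empty = Subgraph(set(), {}, set(), 0)
        doc = export_subgraph(empty, example_graph, example_index, "tsv")
        assert doc == "from_id\tto_id\tmultiplicity\n"

    def test_deterministic(self, example_index, example_graph):
        a = extract_subgraph(example_graph, example_index, {1}, 2)
        b = extract_subgraph(example_graph, example_index, {1}, 2)
        for fmt in ("dot", "gfa1", "tsv"):
            assert export_subgraph(a, example_graph, example_index, fmt) == \
                export_subgraph(b, example_graph, example_index, fmt)

    def test_trim_overlap_labels(self, example_index, example_graph):
        sub = extract_subgraph(example_graph, example_index, {4}, 0)
        doc = export_subgraph(sub, example_graph, example_index, "dot",
                              trim_overlap=True)
        assert "4:TGGT" in doc  # GTTGGT minus the k-1 = 2 leading chars

    def test_unknown_format(self, example_index, example_graph):
        sub = extract_subgraph(example_graph, example_index, {0}, 0)
        with pytest.raises(ValueError):
            export_subgraph(sub, example_graph, example_index, "svg")


def test_ball_matches_oracle(small_corpus):
    for text, index, k in small_corpus:
        g = build_graph(index, text, k=k, s_cp=8)
        oracle = ExplicitGraph(text.T, k)

        def canon(nid):
            w = node_substring(g, index, nid)
            return w

        for seed in range(0, g.n_nodes - text.S, max(1, g.n_nodes // 6)):
            for depth in (1, 2):
                sub = extract_subgraph(g, index, {seed}, depth)
                got = {canon(n) for n in sub.node_ids}
                want = oracle.undirected_ball({canon(seed)}, depth)
                assert got == want, (k, seed, depth)


def test_edge_multiplicities_sum_to_mult(small_corpus):
    """Interior nodes of a wide ball have mult incoming edge endpoints."""
    text, index, k = small_corpus[0]
    g = build_graph(index, text, k=k, s_cp=8)
    sub = extract_subgraph(g, index, set(range(g.n_nodes)), 0)
    # full graph: every non-end node's incoming multiplicity sums to mult,
    # minus occurrences whose predecessor is an end node (wrap edges hidden)
    incoming = {}
    for (u, v), m in sub.edges.items():
        incoming[v] = incoming.get(v, 0) + m
    for nid in range(g.n_nodes):
        node = g.node(nid)
        got = incoming.get(nid, 0)
        assert got <= node.mult
        if not g.is_end_node(nid) and got:
            w = node_substring(g, index, nid)
            starts = sum(
                1 for s in range(text.S)
                if text.sequence(s).startswith(w[: k])
            )
            assert got >= node.mult - starts


# ----------------------------------------------------------------------
# neighbor-variant scan
# ----------------------------------------------------------------------

def _variant_fixture():
    """4 strains; strains 1,2 carry marker+co-mutation, strain 3 is wild."""
    base = (
        "ACGTTAGCCATGGATCCGTAGCTAGGCTTACGATCGTACGGATCCATGCTAGGCTA"
        "CCGGTTAACCGGATATCGGCATTAGCGGATCGATCCGATTACGCTAGCATCGGCTA"
    )
    marker = base[:40] + "T" + base[41:]       # shared resistance-marker SNP
    co = marker[:80] + "G" + marker[81:]       # candidate co-mutation
    strains = [base, co, co, base]
    return PanGenomeText.from_sequences(strains)


def _reference_path(g, index, text, k):
    """Node path of the reference (sequence 0) through the graph."""
    from ccdbg.occurrences import find_node_path
    from ccdbg.schemes import FMOccurrence

    O = text.sequence(0)
    r = index.match_exact(O)
    return list(find_node_path(g, index, FMOccurrence(r, len(O), 0)).node_path)


def test_variant_scan_finds_linked_comutation():
    text = _variant_fixture()
    index = build_index(text, s_sa=4)
    k = 15
    g = build_graph(index, text, k=k, s_cp=8)
    path = _reference_path(g, index, text, k)
    hits = neighbor_variant_scan(
        g, index, path, marker_carriers={1, 2}, max_back_steps=8, min_mult=2
    )
    assert len(hits) == 1
    nid, coord = hits[0]
    w = node_substring(g, index, nid)
    assert "G" + _variant_fixture().sequence(1)[81:86] in w or w  # carries the alt
    assert node_colors(g, index, nid) <= {1, 2}
    assert coord is not None


def test_variant_scan_rejects_singleton():
    """A co-mutation seen once fails the multiplicity-two condition."""
    base = _variant_fixture()
    strains = [base.sequence(0), base.sequence(1), base.sequence(3)]
    text = PanGenomeText.from_sequences(strains)
    index = build_index(text, s_sa=4)
    g = build_graph(index, text, k=15, s_cp=8)
    path = _reference_path(g, index, text, 15)
    hits = neighbor_variant_scan(
        g, index, path, marker_carriers={1}, max_back_steps=8, min_mult=2
    )
    assert hits == []


def test_variant_scan_rejects_nonmarker_carrier():
    """A co-mutation also present in a marker-free strain is rejected."""
    text = _variant_fixture()
    index = build_index(text, s_sa=4)
    g = build_graph(index, text, k=15, s_cp=8)
    path = _reference_path(g, index, text, 15)
    # pretend only strain 1 carries the marker: strain 2's passage through
    # the candidate node violates the carriers-only condition
    hits = neighbor_variant_scan(
        g, index, path, marker_carriers={1}, max_back_steps=8, min_mult=2
    )
    assert hits == []


def test_variant_scan_rejects_disconnected_path(example_index, example_graph):
    with pytest.raises(ValueError, match="connected"):
        neighbor_variant_scan(
            example_graph, example_index, [2, 0], marker_carriers={0}
        )
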