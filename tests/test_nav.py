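"""Navigation operations: worked examples and exhaustive oracle agreement."""

import math

import pytest

from ccdbg import (
    build_graph,
    find_id,
    find_id_left,
    find_id_right,
    get_pred_id_with_char,
    get_succ_id_with_char,
    jump_pred_via_edge,
    node_substring,
)
from ccdbg.fmindex import BoundsError
from ccdbg.nav import UndefinedPositionError, neighbors
from oracles import ExplicitGraph


class TestWorkedExample:
    def test_find_id_right(self, example_graph):
        assert find_id_right(example_graph, 9) == 0   # k-mer GTC
        assert find_id_right(example_graph, 8) == 4   # k-mer GGT
        assert find_id_right(example_graph, 0) == 5   # end-node row

    def test_find_id_left(self, example_graph):
        assert find_id_left(example_graph, 13) == 1   # reverse k-mer TAT
        assert find_id_left(example_graph, 19) == 4   # reverse k-mer TTG
        assert find_id_left(example_graph, 0) == 5

    def test_find_id_with_checkpoints(self, example_index, example_graph):
        ix, g = example_index, example_graph
        p = find_id(g, ix, ix.match_exact("TTG").b)
        assert (p.id, p.offset) == (4, 1)
        p = find_id(g, ix, ix.match_exact("TGG").b)
        assert (p.id, p.offset) == (4, 2)
        p = find_id(g, ix, ix.match_exact("GGT").b)
        assert (p.id, p.offset) == (4, 3)  # offset = len - k

    def test_find_id_row_invariance(self, example_index, example_graph):
        r = example_index.match_exact("TAT")
        results = {
            (p.id, p.offset)
            for p in (
                find_id(example_graph, example_index, row)
                for row in range(r.b, r.e)
            )
        }
        assert results == {(1, 0)}

    def test_pred_succ_with_char(self, example_index, example_graph):
        ix, g = example_index, example_graph
        assert get_pred_id_with_char(g, ix, 1, "A") == 2
        assert get_pred_id_with_char(g, ix, 1, "C") == 3
        assert get_pred_id_with_char(g, ix, 1, "G") is None
        assert get_succ_id_with_char(g, ix, 3, "T") == 1
        assert get_succ_id_with_char(g, ix, 1, "C") == 0
        assert get_succ_id_with_char(g, ix, 1, "A") is None

    def test_jump_pred_via_edge(self, example_index, example_graph):
        ix, g = example_index, example_graph
        assert jump_pred_via_edge(g, ix, 0, 0)[0] == 4
        assert jump_pred_via_edge(g, ix, 0, 1)[0] == 1
        assert jump_pred_via_edge(g, ix, 5, 0)[0] == 0

    def test_cyclic_end_node_edges(self, example_index, example_graph):
        ix, g = example_index, example_graph
        assert get_succ_id_with_char(g, ix, 5, "A") == 3  # $CT -> CTA
        assert get_succ_id_with_char(g, ix, 6, "A") == 2  # %AT -> ATA
        assert get_pred_id_with_char(g, ix, 3, "$") == 5
        assert get_pred_id_with_char(g, ix, 2, "%") == 6

    def test_errors(self, example_index, example_graph):
        with pytest.raises(BoundsError):
            find_id_right(example_graph, 99)
        with pytest.raises(BoundsError):
            jump_pred_via_edge(example_graph, example_index, 0, 2)
        with pytest.raises(IndexError):
            get_pred_id_with_char(example_graph, example_index, 42, "A")
        # row 2 prefixes "ATA..." fine; build a row whose k-mer has an
        # interior separator: suffix "C%..." at row 6
        with pytest.raises(UndefinedPositionError):
            find_id(example_graph, example_index, 6)


def _canon(graph, index, nid):
    """Node key comparable across id relabelings; end nodes merge by string."""
    w = node_substring(graph, index, nid)
    return ("end", w) if graph.is_end_node(nid) else ("node", w)


@pytest.mark.parametrize("s_cp", [1, 2, 8, math.inf])
def test_find_id_matches_oracle_for_every_kmer(small_corpus, s_cp):
    for text, index, k in small_corpus:
        g = build_graph(index, text, k=k, s_cp=s_cp)
        oracle = ExplicitGraph(text.T, k)
        for km, (w, off) in oracle.kmer_pos.items():
            r = index.match_exact(km)
            pos = find_id(g, index, r.b)
            assert _canon(g, index, pos.id)[1] == w, (km, s_cp)
            assert pos.offset == off, (km, w, off, pos, s_cp)


def test_pred_edge_exists_iff_k1mer_exists(small_corpus):
    for text, index, k in small_corpus:
        g = build_graph(index, text, k=k, s_cp=8)
        oracle = ExplicitGraph(text.T, k)
        for nid in range(g.n_nodes):
            if g.is_end_node(nid):
                continue
            w = node_substring(g, index, nid)
            for c in "ACGT":
                pred = get_pred_id_with_char(g, index, nid, c)
                exists = (c + w[: k - 1]) in oracle.kmer_pos and oracle.kmer_pos[
                    c + w[: k - 1]
                ][0] is not None and (c + w[:k]) in text.T
                assert (pred is not None) == exists, (w, c)


def test_jump_enumerates_incoming_edge_multiset(small_corpus):
    for text, index, k in small_corpus:
        g = build_graph(index, text, k=k, s_cp=8)
        oracle = ExplicitGraph(text.T, k)
        for nid in range(g.n_nodes):
            node = g.node(nid)
            w = node_substring(g, index, nid)
            if g.is_end_node(nid) and node.mult > 1 and sum(
                1 for m in range(g.n_nodes)
                if g.is_end_node(m) and node_substring(g, index, m) == w
            ) > 1:
                continue  # duplicated end nodes share their interval
            got = {}
            for off in range(node.mult):
                pid, _ = jump_pred_via_edge(g, index, nid, off)
                key = _canon(g, index, pid)
                got[key] = got.get(key, 0) + 1
            want = {}
            for (a, b), m in oracle.edges.items():
                if b == w:
                    key = ("end", a) if a in oracle.end_omegas else ("node", a)
                    want[key] = want.get(key, 0) + m
            # occurrences at a sequence start (or the text wrap) jump to the
            # previous sequence's end node
            start_occs = node.mult - sum(want.values())
            if start_occs:
                ends = {k_ for k_ in got if k_[0] == "end"}
                for key in list(got):
                    if key[0] == "end" and key not in want:
                        del got[key]
            assert got == want, (w, got, want)


def test_neighbor_sets_match_oracle(small_corpus):
    for text, index, k in small_corpus:
        g = build_graph(index, text, k=k, s_cp=8)
        oracle = ExplicitGraph(text.T, k)
        canon_edges = set()
        for (a, b), _m in oracle.edges.items():
            ka = ("end", a) if a in oracle.end_omegas else ("node", a)
            kb = ("end", b) if b in oracle.end_omegas else ("node", b)
            canon_edges.add((ka, kb))
        for nid in range(g.n_nodes):
            me = _canon(g, index, nid)
            preds, succs = neighbors(g, index, nid, include_separator_chars=False)
            got_p = {_canon(g, index, p) for _c, p in preds}
            got_s = {_canon(g, index, s) for _c, s in succs}
            want_p = {a for (a, b) in canon_edges if b == me}
            assert got_p == want_p, (me, got_p, want_p)
            if g.is_end_node(nid):
                continue  # successors of end nodes are the cyclic wrap edges
            # DNA-only loop cannot enter a length-k end node (separator edge)
            want_s = {
                b for (a, b) in canon_edges
                if a == me and not (b[0] == "end" and len(b[1]) == k)
            }
            assert got_s == want_s, (me, got_s, want_s)
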