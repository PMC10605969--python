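"""Symmetric subgraph extraction, export, and the neighbor-variant scan.

The breadth-first search treats edges as undirected: a node belongs to the
subgraph when its distance to some seed, irrespective of edge orientation,
is at most ``max_depth``.  Edges are recovered by enumerating, for every node
in the ball, its incoming edges through :func:`jump_pred_via_edge`; parallel
edges are collapsed into one edge with a multiplicity.

Cyclic edges — those leaving an end node through the sentinel wrap — are
materialized by the navigation layer but excluded from traversal and export
by default.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .fmindex import BidirectionalIndex
from .graph import ImplicitGraph, node_substring
from .nav import jump_pred_via_edge, neighbors


@dataclass
class Subgraph:
    """A neighborhood ball: node ids, collapsed edges with multiplicities."""

    node_ids: set[int]
    edges: dict[tuple[int, int], int]
    seed_ids: set[int]
    max_depth: int
    depth: dict[int, int] = field(default_factory=dict)


def extract_subgraph(
    graph: ImplicitGraph,
    index: BidirectionalIndex,
    seed_ids,
    max_depth: int,
    include_cyclic: bool = False,
) -> Subgraph:
    """Undirected BFS ball of radius ``max_depth`` around the seeds.

    Nodes discovered at equal depth are processed in ascending id order.
    """
    seed_ids = set(int(s) for s in seed_ids)
    for s in seed_ids:
        graph.node(s)  # raises on unknown seeds
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    depth = {s: 0 for s in seed_ids}
    queue = deque(sorted(seed_ids))
    while queue:
        u = queue.popleft()
        if depth[u] == max_depth:
            continue
        preds, succs = neighbors(graph, index, u, include_separator_chars=True)
        adjacent = set()
        for _c, p in preds:
            if include_cyclic or not graph.is_end_node(p):
                adjacent.add(p)
        for _c, s in succs:
            if include_cyclic or not graph.is_end_node(u):
                adjacent.add(s)
        for v in sorted(adjacent):
            if v not in depth:
                depth[v] = depth[u] + 1
                queue.append(v)
    node_ids = set(depth)

    edges: dict[tuple[int, int], int] = {}
    for v in sorted(node_ids):
        for off in range(graph.node(v).mult):
            u, _back = jump_pred_via_edge(graph, index, v, off)
            if u not in node_ids:
                continue
            if not include_cyclic and graph.is_end_node(u):
                continue  # wrap edge out of an end node
            edges[(u, v)] = edges.get((u, v), 0) + 1
    return Subgraph(
        node_ids=node_ids,
        edges=edges,
        seed_ids=seed_ids,
        max_depth=max_depth,
        depth=depth,
    )


def export_subgraph(
    sub: Subgraph,
    graph: ImplicitGraph,
    index: BidirectionalIndex,
    fmt: str,
    trim_overlap: bool = False,
) -> str:
    """Render a subgraph as ``dot``, ``gfa1`` or ``tsv`` text.

    Node labels carry the node substring; with ``trim_overlap`` the first
    ``k - 1`` characters (the overlap with any predecessor) are dropped from
    the labels.  Output ordering is deterministic (ascending ids).
    """
    k = graph.k
    ids = sorted(sub.node_ids)
    edges = sorted(sub.edges.items())

    def label(nid: int) -> str:
        w = node_substring(graph, index, nid)
        return w[k - 1 :] if trim_overlap else w

    if fmt == "dot":
        lines = ["digraph ccdbg {"]
        for nid in ids:
            shape = ' shape=box' if nid in sub.seed_ids else ""
            lines.append(f'  n{nid} [label="{nid}:{label(nid)}"{shape}];')
        for (u, v), m in edges:
            lines.append(f'  n{u} -> n{v} [label="{m}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "gfa1":
        lines = ["H\tVN:Z:1.0"]
        for nid in ids:
            lines.append(f"S\t{nid}\t{node_substring(graph, index, nid)}")
        for (u, v), m in edges:
            lines.append(f"L\t{u}\t+\t{v}\t+\t{k - 1}M\tRC:i:{m}")
        return "\n".join(lines) + "\n"
    if fmt == "tsv":
        lines = ["from_id\tto_id\tmultiplicity"]
        for (u, v), m in edges:
            lines.append(f"{u}\t{v}\t{m}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown export format {fmt!r} (use dot, gfa1 or tsv)")


def node_colors(
    graph: ImplicitGraph, index: BidirectionalIndex, node_id: int
) -> set[int]:
    """Sequence indices containing at least one occurrence of the node."""
    node = graph.node(node_id)
    return {
        index.text.seq_of(index.sa_value(row))
        for row in range(node.left_kmer, node.left_kmer + node.mult)
    }


def _node_positions_in_seq(
    graph: ImplicitGraph, index: BidirectionalIndex, node_id: int, seq: int
) -> list[int]:
    node = graph.node(node_id)
    text = index.text
    out = []
    for row in range(node.left_kmer, node.left_kmer + node.mult):
        g = index.sa_value(row)
        if text.seq_of(g) == seq:
            out.append(g - text.seq_starts[seq])
    return out


def neighbor_variant_scan(
    graph: ImplicitGraph,
    index: BidirectionalIndex,
    reference_path: list[int],
    marker_carriers,
    max_back_steps: int = 10,
    min_mult: int = 2,
    ref_seq: int = 0,
) -> list[tuple[int, int | None]]:
    """Scan the off-path neighborhood of a reference walk for linked variants.

    A depth-1 neighbor of the walk is a *candidate* when (i) a coordinate in
    the reference sequence could be assigned by walking back through
    predecessors for at most ``max_back_steps`` jumps until a node occurring
    exactly once in sequence ``ref_seq`` is met, (ii) the strains it carries
    are a subset of one marker's carriers, and (iii) its multiplicity is at
    least ``min_mult``.

    ``marker_carriers`` is either one set of sequence indices or a mapping
    ``marker name -> set``; with a mapping, all of a candidate's strains must
    carry the *same* marker.
    """
    if min_mult < 1:
        raise ValueError("min_mult must be >= 1")
    path = [int(u) for u in reference_path]
    path_set = set(path)
    for a, b in zip(path, path[1:]):
        _preds, succs = neighbors(graph, index, a, include_separator_chars=True)
        if b not in {s for _c, s in succs}:
            raise ValueError(f"reference_path is not a connected walk at {a}->{b}")

    if isinstance(marker_carriers, dict):
        carrier_sets = {k: set(v) for k, v in marker_carriers.items()}
    else:
        carrier_sets = {"marker": set(marker_carriers)}

    candidates = set()
    for u in path:
        preds, succs = neighbors(graph, index, u, include_separator_chars=False)
        for _c, v in preds:
            if v not in path_set:
                candidates.add(v)
        for _c, v in succs:
            if v not in path_set:
                candidates.add(v)

    results = []
    for v in sorted(candidates):
        node = graph.node(v)
        if node.mult < min_mult:
            continue
        colors = node_colors(graph, index, v)
        if not any(colors <= cs for cs in carrier_sets.values()):
            continue
        coord = _assign_coordinate(graph, index, v, max_back_steps, ref_seq)
        if coord is None:
            continue
        results.append((v, coord))
    return results


def _assign_coordinate(
    graph: ImplicitGraph,
    index: BidirectionalIndex,
    node_id: int,
    max_back_steps: int,
    ref_seq: int,
) -> int | None:
    """Walk predecessors until a node occurring once in the reference is hit.

    Returns the candidate node's estimated start coordinate in the reference:
    the anchor's occurrence position plus the spelled distance walked.
    """
    k = graph.k
    cur = node_id
    dist = 0
    for _ in range(max_back_steps):
        pid, _off = jump_pred_via_edge(graph, index, cur, 0)
        if graph.is_end_node(pid):
            return None
        dist += graph.node(pid).len - (k - 1)
        pos = _node_positions_in_seq(graph, index, pid, ref_seq)
        if len(pos) == 1:
            return pos[0] + dist
        cur = pid
    return None
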