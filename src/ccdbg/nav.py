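"""Elementary graph navigation on the implicit representation.

All operations work purely on the FM-index, the marker bit vectors and the id
maps; no adjacency is ever materialized.

* ``find_id_right`` / ``find_id_left`` — node id from a row of the SA (resp.
  reverse-SA) interval of a node's rightmost (resp. reversed leftmost) k-mer:
  one rank plus one table lookup.
* ``find_id`` — node id and in-node offset for an *arbitrary* k-mer: walk the
  k-window leftwards with LF from the interval's last row until a marked row
  (checkpoint or rightmost k-mer) is hit; at most ``s_cp - 1`` steps.
* ``get_pred_id_with_char`` / ``get_succ_id_with_char`` — neighbor by
  prepending/appending one character (one FM extension plus one lookup).
* ``jump_pred_via_edge`` — predecessor through one *specific* edge, i.e. by
  extending one specific text occurrence of the node's substring.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import CODE, SIGMA, DNA, SENTINEL, SEPARATOR
from .fmindex import BidirectionalIndex, BoundsError
from .graph import ImplicitGraph


class UndefinedPositionError(ValueError):
    """The requested k-mer has no (resolvable) position in the graph."""


@dataclass(frozen=True)
class NodePosition:
    """A k-mer's unique position: node id and 0-based offset within omega."""

    id: int
    offset: int


def find_id_right(graph: ImplicitGraph, b: int) -> int:
    """Node id for a row of the SA interval of a node's rightmost k-mer.

    Any row of the interval works: the single 1-bit of ``B`` inside the
    interval sits at its last row, so the number of 1-bits strictly before
    ``b`` indexes that bit's entry in ``idmap``.
    """
    if not (0 <= b < graph.B.size):
        raise BoundsError(f"row {b} out of [0, {graph.B.size})")
    return graph.idmap[graph.rank_b(b)][0]


def find_id_left(graph: ImplicitGraph, b_r: int) -> int:
    """Mirror of :func:`find_id_right` over ``B_r``/``idmap_r``."""
    if not (0 <= b_r < graph.B_r.size):
        raise BoundsError(f"row {b_r} out of [0, {graph.B_r.size})")
    return graph.idmap_r[graph.rank_b_r(b_r)]


def _kmer_at_row(graph: ImplicitGraph, index: BidirectionalIndex, row: int) -> str:
    text = index.text
    start = index.sa_value(row)
    k = graph.k
    if start + k <= text.n:
        return text.T[start : start + k]
    return text.T[start:] + text.T[: start + k - text.n]  # rotation window


def find_id(graph: ImplicitGraph, index: BidirectionalIndex, b: int) -> NodePosition:
    """Node id and offset of the k-mer prefixing SA row ``b``.

    ``b`` may be any row of the k-mer's interval; the walk starts from the
    interval's last row (the lexicographically largest suffix with that k-mer
    prefix) and shifts the k-window leftwards with LF until a marked row is
    found.  The queried k-mer's offset is the marked entry's offset plus the
    number of LF steps taken.
    """
    k = graph.k
    km = _kmer_at_row(graph, index, b)
    seps = (SENTINEL, SEPARATOR)
    if any(c in seps for c in km[:-1]):
        raise UndefinedPositionError(
            f"k-mer {km!r} contains an interior separator and is not a graph position"
        )
    r = index.match_exact(km)
    if km[-1] in seps:
        # separator-final k-mer: either a whole length-k end node (resolved
        # through the reverse side) or the last linear k-mer of a longer end
        # node (resolved by the ordinary leftward walk below)
        if graph.rank_b_r(r.e_r) > graph.rank_b_r(r.b_r):
            return NodePosition(find_id_left(graph, r.b_r), 0)
    i = r.e - 1
    steps = 0
    while not graph.B[i]:
        i = index.lf(i)
        steps += 1
        if steps > index.n:
            raise UndefinedPositionError(f"no marked k-mer reachable from {km!r}")
    nid, off = graph.idmap[graph.rank_b(i)]
    node = graph.node(nid)
    query_off = off + steps
    limit = node.len - 1 if node.is_end else node.len - k
    if query_off > limit:
        raise UndefinedPositionError(
            f"k-mer {km!r} cannot be resolved (graph built without checkpoints?)"
        )
    return NodePosition(nid, query_off)


def get_pred_id_with_char(
    graph: ImplicitGraph, index: BidirectionalIndex, node_id: int, c: str
) -> int | None:
    """Predecessor reached by prepending ``c`` to the node's substring.

    Returns ``None`` when the (k+1)-mer ``c + omega[0, k[`` does not occur.
    """
    node = graph.node(node_id)
    code = CODE.get(c)
    if code is None:
        raise UndefinedPositionError(f"character {c!r} outside alphabet {SIGMA!r}")
    b, e = node.left_kmer, node.left_kmer + node.mult
    side = index.fwd
    nb = int(side.C[code]) + side.occ.rank(code, b)
    ne = int(side.C[code]) + side.occ.rank(code, e)
    if nb >= ne:
        return None
    return find_id_right(graph, nb)


def get_succ_id_with_char(
    graph: ImplicitGraph, index: BidirectionalIndex, node_id: int, c: str
) -> int | None:
    """Successor reached by appending ``c`` to the node's rightmost k-mer."""
    node = graph.node(node_id)
    code = CODE.get(c)
    if code is None:
        raise UndefinedPositionError(f"character {c!r} outside alphabet {SIGMA!r}")
    size = 1 if node.is_end else node.mult
    b_r, e_r = node.right_kmer_r, node.right_kmer_r + size
    side = index.rev
    nb = int(side.C[code]) + side.occ.rank(code, b_r)
    ne = int(side.C[code]) + side.occ.rank(code, e_r)
    if nb >= ne:
        return None
    return find_id_left(graph, nb)


def jump_pred_via_edge(
    graph: ImplicitGraph, index: BidirectionalIndex, node_id: int, edge_offset: int
) -> tuple[int, int]:
    """Predecessor through a specific edge.

    ``edge_offset`` selects one text occurrence of the node's substring
    (relative row in ``SA[left_kmer, left_kmer + mult[``).  One LF step lands
    in the predecessor's rightmost-k-mer interval; the returned second value
    is the relative row within that interval, identifying which of the
    predecessor's outgoing edges was traversed backwards.
    """
    node = graph.node(node_id)
    if not (0 <= edge_offset < node.mult):
        raise BoundsError(
            f"edge offset {edge_offset} out of [0, {node.mult}) for node {node_id}"
        )
    i = node.left_kmer + edge_offset
    j = index.lf(i)
    pid = find_id_right(graph, j)
    pred = graph.node(pid)
    if pred.is_end:
        # the cyclic wrap edge out of an end node; its interval is one row
        return pid, 0
    idx = graph.rank_b(j)
    marked_row = int(graph.b_rows[idx])
    left = marked_row + 1 - pred.mult
    return pid, j - left


def neighbors(
    graph: ImplicitGraph,
    index: BidirectionalIndex,
    node_id: int,
    include_separator_chars: bool = True,
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """All (char, id) predecessors and successors of a node.

    With ``include_separator_chars`` the loop covers ``%`` and ``$`` as well,
    which makes the cyclic edges around end nodes discoverable.
    """
    alphabet = SIGMA if include_separator_chars else DNA
    preds, succs = [], []
    for c in alphabet:
        p = get_pred_id_with_char(graph, index, node_id, c)
        if p is not None:
            preds.append((c, p))
        s = get_succ_id_with_char(graph, index, node_id, c)
        if s is not None:
            succs.append((c, s))
    return preds, succs
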