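"""Mapping FM occurrences to graph node paths and text coordinates.

An approximate occurrence ``O`` is an exact substring of the text.  With
``|O| >= k`` it aligns to a unique walk in the graph: the first node comes
from resolving the leftmost k-mer, after which each subsequent node is reached
by jumping to the end of the current node and following the successor edge
labelled with the next character of ``O`` — no per-character re-matching.
Occurrences shorter than ``k`` may sit at several graph positions; these are
enumerated by extending ``O`` to every k-length window that exists in the
text.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import SENTINEL, SEPARATOR
from .fmindex import BidirectionalIndex, BidirectionalRange
from .graph import ImplicitGraph
from .nav import NodePosition, find_id, get_succ_id_with_char
from .pantext import PanGenomeText
from .schemes import FMOccurrence


@dataclass(frozen=True)
class GraphOccurrence:
    """A walk in the graph spelling an occurrence string."""

    node_path: tuple[int, ...]
    start_offset: int
    length: int
    edit_distance: int


@dataclass(frozen=True)
class TextOccurrence:
    """An occurrence located in one of the input sequences."""

    seq_index: int
    start: int
    length: int
    edit_distance: int
    strand: str = "+"
    query_id: str | None = None

    def global_interval(self, text: PanGenomeText) -> tuple[int, int]:
        g = text.seq_starts[self.seq_index] + self.start
        return g, g + self.length


def find_node_path(
    graph: ImplicitGraph, index: BidirectionalIndex, occ: FMOccurrence
) -> GraphOccurrence:
    """Node path of an occurrence with ``|O| >= k`` (unique by construction)."""
    k = graph.k
    if occ.length < k:
        raise ValueError(
            f"occurrence of length {occ.length} < k={k}: use resolve_short_occurrence"
        )
    start = index.sa_value(occ.range.b)
    O = index.text.T[start : start + occ.length]
    first = find_id(graph, index, occ.range.b)
    node = graph.node(first.id)
    path = [first.id]
    covered = node.len - first.offset  # characters of O covered so far
    cur = first.id
    while covered < occ.length:
        nxt = get_succ_id_with_char(graph, index, cur, O[covered])
        if nxt is None:  # cannot happen for an exact substring of T
            raise AssertionError("occurrence walk left the graph")
        path.append(nxt)
        covered += graph.node(nxt).len - (k - 1)
        cur = nxt
    return GraphOccurrence(
        node_path=tuple(path),
        start_offset=first.offset,
        length=occ.length,
        edit_distance=occ.edit_distance,
    )


def resolve_short_occurrence(
    graph: ImplicitGraph, index: BidirectionalIndex, occ: FMOccurrence
) -> list[NodePosition]:
    """All graph start positions of an occurrence shorter than ``k``.

    Enumerates, with the bidirectional index, every k-length extension of
    ``O`` that exists in the text (left extensions over A/C/G/T; the final
    right-extension character may be a separator, reaching windows like
    ``TC%``).  Each window resolves to a node and window offset through
    :func:`find_id`; adding the number of left-extension characters yields
    the start offset of ``O`` itself within that node.  The same position
    reached through several windows is reported once.
    """
    k = graph.k
    if occ.length >= k:
        raise ValueError("occurrence length >= k: use find_node_path")
    need = k - occ.length
    seen: set[NodePosition] = set()

    def extend_right(rng: BidirectionalRange, todo: int, a: int) -> None:
        if todo == 0:
            pos = find_id(graph, index, rng.b)
            seen.add(NodePosition(pos.id, pos.offset + a))
            return
        chars = "ACGT" + (SENTINEL + SEPARATOR if todo == 1 else "")
        for c in chars:
            nr = index.extend_forward(rng, c)
            if not nr.empty:
                extend_right(nr, todo - 1, a)

    # a left-extension characters, k - |O| - a to the right, for every a
    for a in range(need + 1):
        stack = [(occ.range, a)]
        frontier = []
        while stack:
            rng, todo = stack.pop()
            if todo == 0:
                frontier.append(rng)
                continue
            for c in "ACGT":
                nr = index.extend_backward(rng, c)
                if not nr.empty:
                    stack.append((nr, todo - 1))
        for rng in frontier:
            extend_right(rng, need - a, a)
    return sorted(seen, key=lambda p: (p.id, p.offset))


def to_text_occurrences(
    index: BidirectionalIndex,
    text: PanGenomeText,
    occ: FMOccurrence,
    strand: str = "+",
    query_id: str | None = None,
) -> list[TextOccurrence]:
    """One text occurrence per suffix-array row of the occurrence interval."""
    out = []
    for seq, local, _g in index.locate(occ.range):
        out.append(
            TextOccurrence(
                seq_index=seq,
                start=local,
                length=occ.length,
                edit_distance=occ.edit_distance,
                strand=strand,
                query_id=query_id,
            )
        )
    return out


def filter_redundant(occurrences, text: PanGenomeText | None = None):
    """Keep one minimal-edit-distance representative per locus.

    For :class:`FMOccurrence` lists: duplicates (same interval pair and
    length, e.g. found by several searches) collapse to the minimal distance.

    For :class:`TextOccurrence` lists: two occurrences of the same query and
    strand share a locus when their text intervals overlap; candidates are
    ranked by (edit distance, longer length, smaller start) and kept greedily
    if they do not overlap an already kept occurrence.  Idempotent.
    """
    occurrences = list(occurrences)
    if not occurrences:
        return []
    if isinstance(occurrences[0], FMOccurrence):
        best: dict[tuple[int, int, int], FMOccurrence] = {}
        for o in occurrences:
            key = (o.range.b, o.range.e, o.length)
            cur = best.get(key)
            if cur is None or o.edit_distance < cur.edit_distance:
                best[key] = o
        return sorted(
            best.values(), key=lambda o: (o.range.b, o.length, o.edit_distance)
        )
    if text is None:
        raise ValueError("text is required to filter TextOccurrence lists")
    groups: dict[tuple, list[TextOccurrence]] = {}
    for o in occurrences:
        groups.setdefault((o.query_id, o.strand), []).append(o)
    kept_all = []
    for _, group in sorted(groups.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        group.sort(
            key=lambda o: (
                o.edit_distance,
                -o.length,
                o.global_interval(text)[0],
            )
        )
        kept: list[tuple[int, int]] = []
        for o in group:
            g = o.global_interval(text)
            if any(a < g[1] and g[0] < b for a, b in kept):
                continue
            kept.append(g)
            kept_all.append(o)
    kept_all.sort(
        key=lambda o: (str(o.query_id), o.strand, o.seq_index, o.start, -o.length)
    )
    return kept_all
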