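"""Construction of the implicit colored compacted de Bruijn graph.

The graph of a text ``T`` for word length ``k`` has one node per unitig
(maximal non-branching chain of k-mers); k-mers containing a separator
anywhere but their last position are excluded.  Nothing about the edges is
stored: a node table ``G`` (length, multiplicity, and the left bounds of the
suffix-array intervals of its extreme k-mers), two marker bit vectors ``B``
(over SA rows) and ``B_r`` (over reverse-SA rows) and two id maps are enough
to navigate the graph through the FM-index.

``B[i] = 1`` iff the k-mer prefixing row ``i`` is the rightmost k-mer of some
node *or* sits at offset ``j*s_cp`` (``j = 0, 1, ...``) within its node — a
"checkpoint" — and row ``i`` holds the lexicographically largest suffix with
that k-mer prefix.  ``idmap`` maps the rank of each 1-bit to ``(node id,
offset of that k-mer within the node)``.  ``B_r``/``idmap_r`` mirror this for
the reversed leftmost k-mers, without checkpoints.

End nodes: each of the ``S`` sequences contributes its own end node (the
unitig ending in its separator), *even when several sequences end with the
same string*.  An end node's rightmost k-mer is the cyclic window starting at
its separator (wrapping over ``$`` to the start of ``T``), so the first ``S``
bits of ``B`` — the rows of the suffixes starting at separators — mark the end
nodes.

Construction strategy (desk scale): enumerate the valid k-mers explicitly,
compact non-branching chains, then derive every implicit component by
FM-index lookups of the extreme and checkpoint k-mers.  The result is what
matters; the implicit representation is self-contained once built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import SENTINEL, SEPARATOR
from .fmindex import BidirectionalIndex
from .pantext import InputError, PanGenomeText

INF = math.inf


@dataclass
class GraphNode:
    """One ccdBG node; ``omega`` itself is derivable, never stored."""

    len: int
    mult: int
    left_kmer: int
    right_kmer_r: int
    is_end: bool = False
    seq: int | None = None  # owning sequence for end nodes


@dataclass
class ImplicitGraph:
    """The five-component implicit graph representation plus parameters."""

    nodes: list[GraphNode]
    B: np.ndarray          # bool, length n
    B_r: np.ndarray        # bool, length n
    idmap: list[tuple[int, int]]    # per 1-bit of B: (node id, offset)
    idmap_r: list[int]              # per 1-bit of B_r: node id
    k: int
    s_cp: float | None     # checkpoint sparseness; inf = leftmost only,
                           # None = bare baseline without checkpoints
    S: int                 # number of end nodes (== number of sequences)
    b_rows: np.ndarray = field(default=None)    # sorted rows of B's 1-bits
    b_r_rows: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.b_rows is None:
            self.b_rows = np.flatnonzero(self.B)
        if self.b_r_rows is None:
            self.b_r_rows = np.flatnonzero(self.B_r)
        self._rank_b = np.concatenate([[0], np.cumsum(self.B, dtype=np.int64)])
        self._rank_b_r = np.concatenate([[0], np.cumsum(self.B_r, dtype=np.int64)])

    # -- ranks over the marker bit vectors ------------------------------
    def rank_b(self, i: int) -> int:
        """Number of 1-bits of ``B`` strictly before row ``i``."""
        return int(self._rank_b[i])

    def rank_b_r(self, i: int) -> int:
        return int(self._rank_b_r[i])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_checkpoints(self) -> int:
        return int(self.B.sum()) - self.n_nodes

    def is_end_node(self, node_id: int) -> bool:
        return node_id >= self.n_nodes - self.S

    def node(self, node_id: int) -> GraphNode:
        if not (0 <= node_id < self.n_nodes):
            raise IndexError(f"node id {node_id} out of [0, {self.n_nodes})")
        return self.nodes[node_id]


# ----------------------------------------------------------------------
# explicit enumeration helpers
# ----------------------------------------------------------------------

def _valid_kmer_starts(T: str, k: int) -> list[int]:
    """Start positions of k-mers with no separator before their last char."""
    n = len(T)
    sep_after = [n] * (n + 1)  # next separator position at or after i
    nxt = n
    for i in range(n - 1, -1, -1):
        if T[i] in (SENTINEL, SEPARATOR):
            nxt = i
        sep_after[i] = nxt
    return [p for p in range(n - k + 1) if sep_after[p] >= p + k - 1]


def _unitigs(T: str, k: int, forced_starts: set[str]) -> list[str]:
    """Maximal non-branching chains of the k-mer de Bruijn graph of ``T``.

    ``forced_starts`` (the first k-mer of every sequence) always begin a
    chain: a sequence-start k-mer occurs without a valid predecessor window,
    so folding it into the middle of a unitig would break the uniform
    multiplicity that the implicit lookup depends on.
    """
    starts = _valid_kmer_starts(T, k)
    kmers = {T[p : p + k] for p in starts}
    succs: dict[str, set[str]] = {km: set() for km in kmers}
    preds: dict[str, set[str]] = {km: set() for km in kmers}
    valid = set(starts)
    for p in starts:
        if p + 1 in valid:
            a, b = T[p : p + k], T[p + 1 : p + 1 + k]
            succs[a].add(b)
            preds[b].add(a)

    def is_chain_start(km: str) -> bool:
        if km in forced_starts:
            return True
        ps = preds[km]
        if len(ps) != 1:
            return True
        (p,) = ps
        return len(succs[p]) != 1

    out = []
    visited = set()
    for km in sorted(kmers):
        if not is_chain_start(km) or km in visited:
            continue
        chain = [km]
        visited.add(km)
        cur = km
        while len(succs[cur]) == 1:
            (nxt,) = succs[cur]
            if len(preds[nxt]) != 1 or nxt in forced_starts or nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        out.append(chain[0] + "".join(c[-1] for c in chain[1:]))
    # isolated cycles cannot occur in a sentinel-terminated text, but guard
    for km in sorted(kmers):
        if km not in visited:
            chain = [km]
            visited.add(km)
            cur = km
            while True:
                (nxt,) = succs[cur]
                if nxt in visited:
                    break
                chain.append(nxt)
                visited.add(nxt)
                cur = nxt
            out.append(chain[0] + "".join(c[-1] for c in chain[1:]))
    return out


# ----------------------------------------------------------------------
# the builder
# ----------------------------------------------------------------------

def build_graph(
    index: BidirectionalIndex,
    text: PanGenomeText,
    k: int,
    s_cp: float = 128,
) -> ImplicitGraph:
    """Build the implicit ccdBG for word length ``k``.

    ``s_cp`` is the checkpoint sparseness: besides each node's rightmost
    k-mer, the k-mers at in-node offsets ``0, s_cp, 2*s_cp, ...`` (strictly
    below ``len - k``) are marked in ``B`` so that any k-mer resolves to its
    node within ``s_cp - 1`` LF steps.  ``math.inf`` keeps only the offset-0
    mark (the ``j = 0`` checkpoint), degrading lookup to one walk over the
    node length but keeping it correct.  ``None`` builds the bare baseline
    (rightmost-k-mer marks only); then only extreme k-mers can be resolved.

    Node ids are canonical: nodes with multiplicity >= 2 first, then the
    remaining non-end nodes, each group ordered by the SA row of its
    rightmost-k-mer mark; the ``S`` end nodes come last, ordered by their
    separator row.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    for s in range(text.S):
        if text.seq_length(s) < k:
            raise InputError(
                f"sequence {text.seq_names[s]!r} is shorter than k={k}"
            )
    if s_cp is not None and s_cp != INF:
        s_cp = int(s_cp)
        if s_cp < 1:
            raise InputError("s_cp must be >= 1 (or infinity, or None)")

    T, n = text.T, text.n

    # explicit unitigs, then per-sequence end-node split
    forced = {T[st : st + k] for st in text.seq_starts}
    omegas = _unitigs(T, k, forced)
    sep_positions = text.separator_positions()
    end_omega_of_seq: dict[int, str] = {}
    by_end_kmer = {w[-k:]: w for w in omegas if w[-1] in (SENTINEL, SEPARATOR)}
    for s, sep in enumerate(sep_positions):
        end_omega_of_seq[s] = by_end_kmer[T[sep - k + 1 : sep + 1]]
    end_omegas = set(end_omega_of_seq.values())
    interior_omegas = [w for w in omegas if w not in end_omegas]

    # provisional records: (omega, is_end, seq)
    recs: list[tuple[str, bool, int | None]] = [
        (w, False, None) for w in interior_omegas
    ]
    for s in range(text.S):
        recs.append((end_omega_of_seq[s], True, s))

    # FM lookups per record
    raw_nodes: list[GraphNode] = []
    mark_row: list[int] = []        # row of the rightmost-k-mer / end mark
    for w, is_end, s in recs:
        rw = index.match_exact(w)
        mult = rw.size
        left_kmer = rw.b
        if is_end:
            sep = sep_positions[s]
            row = index.isa_of_separator(sep)
            rkr = int(index.isa_r[(n - sep - k) % n])
        else:
            rk = index.match_exact(w[-k:])
            row = rk.e - 1
            rkr = rk.b_r
        raw_nodes.append(
            GraphNode(len(w), mult, left_kmer, rkr, is_end=is_end, seq=s)
        )
        mark_row.append(row)

    # canonical id order
    order = sorted(
        range(len(raw_nodes)),
        key=lambda i: (
            2 if raw_nodes[i].is_end else (0 if raw_nodes[i].mult >= 2 else 1),
            mark_row[i],
        ),
    )
    nodes = [raw_nodes[i] for i in order]
    rows = [mark_row[i] for i in order]
    omega_of = {nid: recs[order[nid]][0] for nid in range(len(nodes))}

    # B and idmap: rightmost/end marks plus checkpoints
    entries: dict[int, tuple[int, int]] = {}
    for nid, node in enumerate(nodes):
        off = node.len - 1 if node.is_end else node.len - k
        entries.setdefault(rows[nid], (nid, off))
        w = omega_of[nid]
        ncp = node.len - k  # checkpoint offsets must stay strictly below this
        if ncp > 0 and s_cp is not None:
            if s_cp == INF:
                offs = [0]
            else:
                offs = range(0, ncp, s_cp)
            for o in offs:
                km = w[o : o + k]
                r = index.match_exact(km)
                entries.setdefault(r.e - 1, (nid, o))

    b_rows_sorted = sorted(entries)
    B = np.zeros(n, dtype=bool)
    B[b_rows_sorted] = True
    idmap = [entries[r] for r in b_rows_sorted]

    # B_r and idmap_r: reversed leftmost k-mers; duplicate-omega end nodes
    # share an interval and receive its top rows, lowest id lowest row
    entries_r: dict[int, int] = {}
    groups: dict[tuple[int, int], list[int]] = {}
    for nid, node in enumerate(nodes):
        w = omega_of[nid]
        rr = index.match_exact(w[:k])
        groups.setdefault((rr.b_r, rr.e_r), []).append(nid)
    for (b_r, e_r), ids in groups.items():
        ids.sort()
        if len(ids) > e_r - b_r:
            raise AssertionError("more nodes than rows in a leftmost interval")
        top = range(e_r - len(ids), e_r)
        for row, nid in zip(top, ids):
            entries_r[row] = nid
    b_r_rows_sorted = sorted(entries_r)
    B_r = np.zeros(n, dtype=bool)
    B_r[b_r_rows_sorted] = True
    idmap_r = [entries_r[r] for r in b_r_rows_sorted]

    return ImplicitGraph(
        nodes=nodes,
        B=B,
        B_r=B_r,
        idmap=idmap,
        idmap_r=idmap_r,
        k=k,
        s_cp=s_cp,
        S=text.S,
        b_rows=np.asarray(b_rows_sorted, dtype=np.int64),
        b_r_rows=np.asarray(b_r_rows_sorted, dtype=np.int64),
    )


def node_substring(graph: ImplicitGraph, index: BidirectionalIndex, node_id: int) -> str:
    """The node's substring ``omega = T[SA[left_kmer], SA[left_kmer]+len[``."""
    node = graph.node(node_id)
    start = index.sa_value(node.left_kmer)
    return index.text.T[start : start + node.len]
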