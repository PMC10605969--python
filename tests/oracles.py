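"""Independent brute-force oracles used to validate the implicit structures.

Everything here works directly on the plain text with naive enumeration or
dynamic programming (networkx for the explicit graph), never through the
FM-index machinery it is checking.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

SEPS = ("$", "%")


# ----------------------------------------------------------------------
# explicit ccdBG
# ----------------------------------------------------------------------

class ExplicitGraph:
    """Explicit compacted de Bruijn graph built by direct k-mer enumeration.

    Nodes are unitig strings.  Per-sequence end-node duplication is *merged*
    (one node per distinct end unitig string): the implicit navigation layer
    resolves equal-string end nodes to one canonical representative, so graph
    comparisons work on this merged view.
    """

    def __init__(self, T: str, k: int):
        self.T, self.k = T, k
        n = len(T)
        valid = [
            p
            for p in range(n - k + 1)
            if all(c not in SEPS for c in T[p : p + k - 1])
        ]
        self.valid_positions = valid
        kmers = sorted({T[p : p + k] for p in valid})
        g = nx.DiGraph()
        g.add_nodes_from(kmers)
        vset = set(valid)
        edge_count: dict[tuple[str, str], int] = {}
        for p in valid:
            if p + 1 in vset:
                a, b = T[p : p + k], T[p + 1 : p + 1 + k]
                g.add_edge(a, b)
                edge_count[(a, b)] = edge_count.get((a, b), 0) + 1

        seq_start_kmers = {
            T[p : p + k]
            for p in range(n - k + 1)
            if p == 0 or T[p - 1] in SEPS
        }

        def chain_start(km):
            if km in seq_start_kmers:
                return True
            ps = list(g.predecessors(km))
            return len(ps) != 1 or g.out_degree(ps[0]) != 1

        unitigs = []
        seen = set()
        for km in kmers:
            if km in seen or not chain_start(km):
                continue
            chain = [km]
            seen.add(km)
            cur = km
            while g.out_degree(cur) == 1:
                (nxt,) = g.successors(cur)
                if g.in_degree(nxt) != 1 or nxt in seq_start_kmers or nxt in seen:
                    break
                chain.append(nxt)
                seen.add(nxt)
                cur = nxt
            unitigs.append(chain)
        for km in kmers:  # safety: isolated cycles
            if km not in seen:
                chain = [km]
                seen.add(km)
                cur = km
                while True:
                    (nxt,) = g.successors(cur)
                    if nxt in seen:
                        break
                    chain.append(nxt)
                    seen.add(nxt)
                    cur = nxt
                unitigs.append(chain)

        self.omega = {}       # unitig string -> list of member k-mers
        self.kmer_pos = {}    # k-mer -> (unitig string, offset)
        for chain in unitigs:
            w = chain[0] + "".join(c[-1] for c in chain[1:])
            self.omega[w] = chain
            for off, km in enumerate(chain):
                self.kmer_pos[km] = (w, off)

        # occurrence counts (overlapping)
        self.mult = {}
        for w in self.omega:
            cnt = start = 0
            while True:
                i = T.find(w, start)
                if i < 0:
                    break
                cnt += 1
                start = i + 1
            self.mult[w] = cnt

        # unitig-level edges with multiplicities ((k+1)-mer counts)
        self.edges: dict[tuple[str, str], int] = {}
        for (a, b), m in edge_count.items():
            wa, _ = self.kmer_pos[a]
            wb, offb = self.kmer_pos[b]
            # only unitig-boundary edges survive compaction
            if self.kmer_pos[a][1] == len(self.omega[wa]) - 1 and offb == 0:
                self.edges[(wa, wb)] = self.edges.get((wa, wb), 0) + m

        self.end_omegas = {w for w in self.omega if w[-1] in SEPS}

    # -- queries --------------------------------------------------------
    def node_of_kmer(self, km: str) -> tuple[str, int]:
        return self.kmer_pos[km]

    def positions_of_short(self, O: str) -> set[tuple[str, int]]:
        """(unitig, start offset) pairs where a string shorter than k occurs
        at a position covered by some valid k-window."""
        out = set()
        T, k = self.T, self.k
        vset = set(self.valid_positions)
        start = 0
        while True:
            p = self.T.find(O, start)
            if p < 0:
                break
            start = p + 1
            for a in range(k - len(O) + 1):
                wstart = p - a
                if wstart in vset:
                    w, off = self.kmer_pos[T[wstart : wstart + k]]
                    out.add((w, off + a))
        return out

    def undirected_ball(self, seeds: set[str], depth: int) -> set[str]:
        u = nx.MultiDiGraph()
        for (a, b), m in self.edges.items():
            for _ in range(m):
                u.add_edge(a, b)
        u.add_nodes_from(self.omega)
        ug = u.to_undirected()
        out = set()
        for s in seeds:
            out |= {
                v
                for v, d in nx.single_source_shortest_path_length(
                    ug, s, cutoff=depth
                ).items()
            }
        return out


# ----------------------------------------------------------------------
# brute-force approximate matching
# ----------------------------------------------------------------------

def banded_candidates(seq: str, P: str, K: int) -> list[tuple[int, int, int]]:
    """All (start, length, ED(seq[start:start+length], P)) with ED <= K.

    Vectorized over start positions; band ``|length - |P|| <= K``.
    """
    n, m = len(seq), len(P)
    if n == 0 or m == 0:
        return []
    sc = np.frombuffer(seq.encode(), dtype=np.uint8)
    pc = np.frombuffer(P.encode(), dtype=np.uint8)
    big = 1 << 20
    # cost[d][s] = ED(P[:i], seq[s:s+i+d]) for diagonal offset d in [-K, K]
    cost = {d: np.full(n + 1, big, dtype=np.int32) for d in range(-K, K + 1)}
    for d in range(0, K + 1):
        cost[d][:] = d  # i = 0: j = d deletions from the pattern side
    results = []
    for i in range(1, m + 1):
        prev = cost
        cost = {d: np.full(n + 1, big, dtype=np.int32) for d in range(-K, K + 1)}
        for d in range(-K, K + 1):
            j = i + d
            if j < 0 or j > n:
                continue
            best = np.full(n + 1, big, dtype=np.int32)
            if j == 0:
                best[:] = i
                cost[d] = best
                continue
            # vertical: skip pattern char (prev diagonal d+... j same, i-1 -> d+1)
            if d + 1 <= K:
                np.minimum(best, prev[d + 1] + 1, out=best)
            # horizontal: consume seq char, i same (cost[d-1] this row)
            if d - 1 >= -K and i + d - 1 >= 0:
                np.minimum(best, cost[d - 1] + 1, out=best)
            # diagonal
            sub = prev[d].copy()
            lim = n - j + 1
            if lim > 0:
                mism = (sc[j - 1 : j - 1 + lim] != pc[i - 1]).astype(np.int32)
                sub[:lim] += mism
                sub[lim:] = big
                np.minimum(best, sub, out=best)
            cost[d] = best
        if i == m:
            for d in range(-K, K + 1):
                l = m + d
                if l <= 0 or l > n:
                    continue
                col = cost[d]
                for s in np.flatnonzero(col[: n - l + 1] <= K):
                    results.append((int(s), l, int(col[s])))
    return results


def oracle_text_occurrences(text, P: str, K: int) -> set[tuple[int, int, int, int]]:
    """{(seq, start, length, ed)} over all sequences; the exhaustive truth."""
    out = set()
    for s in range(text.S):
        for st, ln, ed in banded_candidates(text.sequence(s), P, K):
            out.add((s, st, ln, ed))
    return out


def oracle_filtered(text, P: str, K: int) -> list[tuple[int, int, int, int]]:
    """The exhaustive candidates run through the same greedy locus filter."""
    cands = sorted(
        oracle_text_occurrences(text, P, K),
        key=lambda c: (c[3], -c[2], text.seq_starts[c[0]] + c[1]),
    )
    kept, ivals = [], []
    for s, st, ln, ed in cands:
        g0 = text.seq_starts[s] + st
        g1 = g0 + ln
        if any(a < g1 and g0 < b for a, b in ivals):
            continue
        ivals.append((g0, g1))
        kept.append((s, st, ln, ed))
    return sorted(kept)
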