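"""Bidirectional FM-index of the pan-genome text.

Both the text ``T`` and its full reversal ``T^r`` (sentinel included) are
indexed.  A partial match is carried as a *pair* of synchronized half-open
suffix-array intervals — ``[b, e[`` over ``SA`` for the pattern ``P`` and
``[b_r, e_r[`` over ``SA^r`` for ``P`` reversed — so it can be extended by one
character to the left (``extend_backward``) or to the right
(``extend_forward``) in constant time.

Because patterns are matched purely through LF-type character extensions
(never by direct suffix comparison), matching follows *rotation* semantics:
a pattern that runs over the final sentinel wraps around to the start of the
text.  Ordinary DNA patterns are unaffected (any wrap crosses the unique
``$``), but the graph layer exploits the wrap to give the per-sequence end
nodes their cyclically extended rightmost k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import CODE, SIGMA, SIGMA_SIZE, AlphabetError, decode
from .pantext import PanGenomeText


class BoundsError(IndexError):
    """A suffix-array row outside ``[0, n[`` was requested."""


# ----------------------------------------------------------------------
# suffix array construction (prefix doubling, numpy)
# ----------------------------------------------------------------------

def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling; O(n log^2 n), adequate at desk scale."""
    n = codes.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        new_rank = np.empty(n, dtype=np.int64)
        diff = (rank[order[1:]] != rank[order[:-1]]) | (
            second[order[1:]] != second[order[:-1]]
        )
        new_rank[order[0]] = 0
        new_rank[order[1:]] = np.cumsum(diff)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            break
        k <<= 1
    return order


# ----------------------------------------------------------------------
# rank support
# ----------------------------------------------------------------------

class RankTable:
    """Per-character occurrence counts over a BWT string.

    ``rank(c, i)`` = number of occurrences of character code ``c`` in
    ``bwt[0, i[``.  Counts are checkpointed every ``block`` positions; with
    the default ``block=1`` the full prefix-count table is stored, making
    every rank a single array access.
    """

    def __init__(self, bwt_codes: np.ndarray, block: int = 1):
        self.block = int(block)
        self.n = bwt_codes.size
        onehot = np.zeros((self.n + 1, SIGMA_SIZE), dtype=np.int32)
        idx = np.arange(self.n)
        onehot[idx + 1, bwt_codes] = 1
        full = np.cumsum(onehot, axis=0, dtype=np.int32)
        if self.block == 1:
            self._table = full
        else:
            self._table = full[:: self.block].copy()
            self._bwt = bwt_codes
        self.totals = full[-1].copy()

    def rank(self, c: int, i: int) -> int:
        if self.block == 1:
            return int(self._table[i, c])
        q, r = divmod(i, self.block)
        cnt = int(self._table[q, c])
        if r:
            cnt += int(np.count_nonzero(self._bwt[q * self.block : i] == c))
        return cnt

    def rank_all(self, i: int) -> np.ndarray:
        """Ranks of all six characters at once."""
        if self.block == 1:
            return self._table[i]
        q, r = divmod(i, self.block)
        cnt = self._table[q].copy()
        if r:
            cnt += np.bincount(
                self._bwt[q * self.block : i], minlength=SIGMA_SIZE
            ).astype(np.int32)
        return cnt


# ----------------------------------------------------------------------
# ranges
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BidirectionalRange:
    """Synchronized SA / reverse-SA intervals of a partial match."""

    b: int
    e: int
    b_r: int
    e_r: int

    @property
    def size(self) -> int:
        return self.e - self.b

    @property
    def empty(self) -> bool:
        return self.e <= self.b

    def __post_init__(self):
        if self.e - self.b != self.e_r - self.b_r:
            raise ValueError("forward and reverse intervals must have equal size")


EMPTY_RANGE = BidirectionalRange(0, 0, 0, 0)


# ----------------------------------------------------------------------
# the index
# ----------------------------------------------------------------------

class _Side:
    """One direction of the index: BWT, rank table, sparse SA."""

    def __init__(self, codes: np.ndarray, s_sa: int, block: int):
        n = codes.size
        self.sa_full = suffix_array(codes)  # kept only transiently by callers
        sa = self.sa_full
        self.bwt = codes[(sa - 1) % n]
        self.occ = RankTable(self.bwt, block=block)
        counts = np.bincount(codes, minlength=SIGMA_SIZE)
        self.C = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
        # sparse SA: keep rows whose SA value is a multiple of s_sa
        self.s_sa = s_sa
        mark = (sa % s_sa) == 0
        self.sa_mark = np.packbits(mark)
        self._mark_bool = mark
        self.sa_mark_rank = np.concatenate(
            [[0], np.cumsum(mark, dtype=np.int64)]
        )
        self.sa_samples = sa[mark].astype(np.int64)
        self.n = n

    def lf(self, i: int) -> int:
        c = int(self.bwt[i])
        return int(self.C[c]) + self.occ.rank(c, i)

    def sa_value(self, i: int) -> int:
        steps = 0
        while not self._mark_bool[i]:
            i = self.lf(i)
            steps += 1
        return int(self.sa_samples[self.sa_mark_rank[i]]) + steps


class BidirectionalIndex:
    """Bidirectional FM-index over a :class:`PanGenomeText`.

    Attributes mirror the classical layout: ``bwt``/``bwt_r`` with rank
    support, cumulative character counts, and sparse suffix arrays with
    sparseness factor ``s_sa`` (one factor serves both directions).
    """

    def __init__(self, text: PanGenomeText, s_sa: int = 16, rank_block: int = 1):
        if s_sa < 1:
            raise ValueError("s_sa must be >= 1")
        self.text = text
        self.n = text.n
        self.s_sa = s_sa
        codes = text.codes
        self.fwd = _Side(codes, s_sa, rank_block)
        self.rev = _Side(codes[::-1].copy(), s_sa, rank_block)
        # inverse permutations; the graph builder uses them to pin the
        # per-sequence end-node rows (k-dependent, so kept in full)
        self.isa = np.empty(self.n, dtype=np.int64)
        self.isa[self.fwd.sa_full] = np.arange(self.n)
        self.isa_r = np.empty(self.n, dtype=np.int64)
        self.isa_r[self.rev.sa_full] = np.arange(self.n)
        self._isa_sep = {int(p): int(self.isa[p]) for p in text.separator_positions()}

    # -- basic accessors -------------------------------------------------
    @property
    def bwt(self) -> str:
        return decode(self.fwd.bwt)

    @property
    def bwt_r(self) -> str:
        return decode(self.rev.bwt)

    def sa_value(self, i: int, reverse: bool = False) -> int:
        """Full SA value at row ``i``, recovered from the sparse samples."""
        if not (0 <= i < self.n):
            raise BoundsError(f"row {i} out of [0, {self.n})")
        side = self.rev if reverse else self.fwd
        return side.sa_value(i)

    def lf(self, i: int, reverse: bool = False) -> int:
        """Row ``j`` with ``SA[j] = SA[i] - 1 (mod n)``."""
        if not (0 <= i < self.n):
            raise BoundsError(f"row {i} out of [0, {self.n})")
        side = self.rev if reverse else self.fwd
        return side.lf(i)

    def full_range(self) -> BidirectionalRange:
        return BidirectionalRange(0, self.n, 0, self.n)

    # -- extensions ------------------------------------------------------
    def _extend(self, r: BidirectionalRange, c: int, forward: bool) -> BidirectionalRange:
        if r.empty:
            return EMPTY_RANGE
        if forward:
            side = self.rev
            b, e, b2s, = r.b_r, r.e_r, r.b
        else:
            side = self.fwd
            b, e, b2s = r.b, r.e, r.b_r
        lo = side.occ.rank_all(b)
        hi = side.occ.rank_all(e)
        nb = int(side.C[c]) + int(lo[c])
        ne = int(side.C[c]) + int(hi[c])
        if nb >= ne:
            return EMPTY_RANGE
        smaller = int((hi[:c] - lo[:c]).sum())
        ob = b2s + smaller
        oe = ob + (ne - nb)
        if forward:
            return BidirectionalRange(ob, oe, nb, ne)
        return BidirectionalRange(nb, ne, ob, oe)

    def _check_char(self, c: str) -> int:
        code = CODE.get(c)
        if code is None:
            raise AlphabetError(f"character {c!r} is outside alphabet {SIGMA!r}")
        return code

    def extend_backward(self, r: BidirectionalRange, c: str) -> BidirectionalRange:
        """Range of ``cP`` given the range of ``P``."""
        return self._extend(r, self._check_char(c), forward=False)

    def extend_forward(self, r: BidirectionalRange, c: str) -> BidirectionalRange:
        """Range of ``Pc`` given the range of ``P``."""
        return self._extend(r, self._check_char(c), forward=True)

    def extend_backward_code(self, r: BidirectionalRange, c: int) -> BidirectionalRange:
        return self._extend(r, c, forward=False)

    def extend_forward_code(self, r: BidirectionalRange, c: int) -> BidirectionalRange:
        return self._extend(r, c, forward=True)

    # -- matching and locating ------------------------------------------
    def match_exact(self, pattern: str) -> BidirectionalRange:
        """Range of all (rotation) occurrences of ``pattern`` in ``T``."""
        r = self.full_range()
        for c in reversed(pattern):
            r = self.extend_backward(r, c)
            if r.empty:
                return EMPTY_RANGE
        return r

    def locate(
        self, r: BidirectionalRange, length: int | None = None
    ) -> list[tuple[int, int, int]]:
        """(sequence index, local position, global position) per row of ``r``.

        The sequence index is the largest ``s`` with
        ``seq_starts[s] <= global``; ``local = global - seq_starts[s]``.
        """
        out = []
        for i in range(r.b, r.e):
            g = self.fwd.sa_value(i)
            s = self.text.seq_of(g)
            out.append((s, g - self.text.seq_starts[s], g))
        return out

    # -- helpers for the graph layer ------------------------------------
    def isa_of_separator(self, sep_pos: int) -> int:
        """SA row of the suffix starting at a separator position."""
        return self._isa_sep[sep_pos]


def build_index(
    text: PanGenomeText, s_sa: int = 16, rank_block: int = 1
) -> BidirectionalIndex:
    """Build the bidirectional FM-index (library suffix sort at desk scale)."""
    return BidirectionalIndex(text, s_sa=s_sa, rank_block=rank_block)
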