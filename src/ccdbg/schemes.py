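"""Search schemes: lossless approximate matching on the bidirectional index.

A search ``S = (pi, L, U)`` processes the ``p`` parts of a pattern in the
order given by the permutation ``pi`` (which must grow a contiguous span, so
each step extends the partial match left or right), keeping the cumulative
number of errors after each part within ``[L[i], U[i]]``.  A *scheme* is a set
of searches that together cover every distribution of at most ``K`` errors
over the parts, which makes the procedure lossless: every occurrence ``O`` of
``P`` in ``T`` with ``ED(O, P) <= K`` is found.

Execution uses one banded dynamic-programming matrix per part, anchored at
the part boundary where processing starts; every admissible boundary state
(occurrence length consumed, cumulative cost) spawns the next part.  Since
edit distance decomposes at part boundaries
(``ED(XY, O) = min over O = O1 O2 of ED(X, O1) + ED(Y, O2)``) and the scheme
covers every error vector, the optimal decomposition of every occurrence is
explored by at least one search, so each occurrence is reported at its
minimal edit distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .alphabet import DNA
from .fmindex import BidirectionalIndex, BidirectionalRange

MAX_K = 4
_BIG = 1 << 30


class SchemeError(ValueError):
    """Structurally invalid or incomplete search scheme."""


# ----------------------------------------------------------------------
# scheme objects
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Search:
    """One search: processing order ``pi`` with cumulative bounds ``L``/``U``."""

    pi: tuple[int, ...]
    L: tuple[int, ...]
    U: tuple[int, ...]

    def __post_init__(self):
        p = len(self.pi)
        if not (len(self.L) == len(self.U) == p):
            raise SchemeError("pi, L and U must have equal length")
        if sorted(self.pi) != list(range(p)):
            raise SchemeError(f"pi={self.pi} is not a permutation of 0..{p - 1}")
        lo = hi = self.pi[0]
        for x in self.pi[1:]:
            if x == hi + 1:
                hi = x
            elif x == lo - 1:
                lo = x
            else:
                raise SchemeError(
                    f"pi={self.pi} violates connectivity (part {x} is not "
                    "adjacent to the processed span)"
                )
        for name, arr in (("L", self.L), ("U", self.U)):
            if any(arr[i] > arr[i + 1] for i in range(p - 1)):
                raise SchemeError(f"{name}={arr} must be non-decreasing")
        if any(l > u for l, u in zip(self.L, self.U)):
            raise SchemeError("L must be pointwise <= U")

    @property
    def p(self) -> int:
        return len(self.pi)

    def covers(self, errors: tuple[int, ...]) -> bool:
        """Whether the error vector's prefix sums in pi-order satisfy L/U."""
        acc = 0
        for i, part in enumerate(self.pi):
            acc += errors[part]
            if not (self.L[i] <= acc <= self.U[i]):
                return False
        return True


@dataclass(frozen=True)
class Scheme:
    """A set of searches jointly covering all <=K-error distributions."""

    K: int
    searches: tuple[Search, ...]

    def __post_init__(self):
        if not self.searches:
            raise SchemeError("a scheme needs at least one search")
        p = self.searches[0].p
        if any(s.p != p for s in self.searches):
            raise SchemeError("all searches must use the same number of parts")
        if any(s.U[-1] > self.K for s in self.searches):
            raise SchemeError("U[p-1] may not exceed K")

    @property
    def p(self) -> int:
        return self.searches[0].p


@dataclass(frozen=True)
class FMOccurrence:
    """An approximate occurrence as its interval pair, length and distance."""

    range: BidirectionalRange
    length: int
    edit_distance: int


# ----------------------------------------------------------------------
# canonical schemes
# ----------------------------------------------------------------------

def pigeonhole_scheme(K: int) -> Scheme:
    """The K+1-part scheme where search i anchors part i error-free.

    Each search matches its anchor part exactly, extends leftward down to
    part 0, then rightward to the end, allowing up to K errors once the
    anchor is processed.
    """
    if not (0 <= K <= MAX_K):
        raise SchemeError(f"K must be within 0..{MAX_K}, got {K}")
    p = K + 1
    searches = []
    for i in range(p):
        pi = tuple(range(i, -1, -1)) + tuple(range(i + 1, p))
        L = (0,) * p
        U = (0,) + (K,) * (p - 1)
        searches.append(Search(pi, L, U))
    return Scheme(K=K, searches=tuple(searches))


def kucherov_k2_scheme() -> Scheme:
    """The three-search two-error scheme with tightened bounds."""
    return Scheme(
        K=2,
        searches=(
            Search((0, 1, 2), (0, 1, 2), (0, 2, 2)),
            Search((2, 1, 0), (0, 0, 0), (0, 1, 2)),
            Search((1, 0, 2), (0, 0, 1), (0, 1, 2)),
        ),
    )


def load_scheme(path) -> Scheme:
    """Parse a scheme file: header line ``p K``, then one search per line.

    Each search line holds three whitespace-separated digit strings: the
    permutation, the lower bounds and the upper bounds.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise SchemeError("empty scheme file")
    head = lines[0].split()
    if len(head) != 2:
        raise SchemeError(f"header must be 'p K', got {lines[0]!r}")
    p, K = int(head[0]), int(head[1])
    searches = []
    for ln in lines[1:]:
        cols = ln.split()
        if len(cols) != 3 or any(len(c) != p or not c.isdigit() for c in cols):
            raise SchemeError(f"malformed search line {ln!r} (expected 3 "
                              f"digit strings of length {p})")
        pi, L, U = (tuple(int(d) for d in c) for c in cols)
        searches.append(Search(pi, L, U))
    scheme = Scheme(K=K, searches=tuple(searches))
    if scheme.p != p:
        raise SchemeError("search length disagrees with header")
    ok, uncovered = validate_scheme(scheme, K)
    if not ok:
        raise SchemeError(
            f"scheme does not cover error distributions: {uncovered[:5]}"
        )
    return scheme


def validate_scheme(scheme: Scheme, K: int) -> tuple[bool, list[tuple[int, ...]]]:
    """Check coverage of every error vector with sum <= K over p parts."""
    p = scheme.p
    uncovered = []
    for vec in product(range(K + 1), repeat=p):
        if sum(vec) > K:
            continue
        if not any(s.covers(vec) for s in scheme.searches):
            uncovered.append(vec)
    return (not uncovered), uncovered


def partition_pattern(P: str, p: int) -> list[str]:
    """Uniform contiguous partition; the remainder goes to the leftmost parts."""
    if len(P) < p:
        raise ValueError(f"pattern of length {len(P)} cannot be split in {p} parts")
    q, r = divmod(len(P), p)
    parts, pos = [], 0
    for i in range(p):
        ln = q + (1 if i < r else 0)
        parts.append(P[pos : pos + ln])
        pos += ln
    return parts


# ----------------------------------------------------------------------
# execution
# ----------------------------------------------------------------------

def _phase_plan(search: Search, parts: list[str]) -> list[tuple[str, bool, int, int]]:
    """(segment, forward?, L_i, U_i) per processed part, segments oriented
    in extension order (leftward segments reversed)."""
    plan = []
    lo = hi = search.pi[0]
    plan.append((parts[search.pi[0]], True, search.L[0], search.U[0]))
    for i, part in enumerate(search.pi[1:], start=1):
        if part == hi + 1:
            plan.append((parts[part], True, search.L[i], search.U[i]))
            hi = part
        else:
            plan.append((parts[part][::-1], False, search.L[i], search.U[i]))
            lo = part
    return plan


def _run_search(
    index: BidirectionalIndex,
    plan: list[tuple[str, bool, int, int]],
    K: int,
    out: dict[tuple[int, int, int], tuple[int, BidirectionalRange]],
) -> None:
    extendf = index.extend_forward_code
    extendb = index.extend_backward_code
    from .alphabet import CODE

    dna_codes = [(c, CODE[c]) for c in DNA]
    n_phases = len(plan)

    def phase(idx: int, rng: BidirectionalRange, e0: int, occ_len: int) -> None:
        seg, fwd, L_i, U_i = plan[idx]
        m = len(seg)
        ext = extendf if fwd else extendb
        # row over columns 0..m; start state: no occurrence chars consumed
        row = [min(e0 + j, _BIG) for j in range(m + 1)]

        def visit(rng_, row_, t) -> None:
            v = row_[m]
            if L_i <= v <= U_i:
                if idx == n_phases - 1:
                    if occ_len + t > 0:
                        key = (rng_.b, rng_.e, occ_len + t)
                        prev = out.get(key)
                        if prev is None or v < prev[0]:
                            out[key] = (v, rng_)
                else:
                    phase(idx + 1, rng_, v, occ_len + t)
            if t - m >= K:  # no cell can improve below the band
                return
            for ch, code in dna_codes:
                nr = ext(rng_, code)
                if nr.empty:
                    continue
                new = [row_[0] + 1] + [0] * m
                best = new[0]
                for j in range(1, m + 1):
                    c = min(
                        new[j - 1] + 1,
                        row_[j] + 1,
                        row_[j - 1] + (0 if seg[j - 1] == ch else 1),
                    )
                    new[j] = c
                    if c < best:
                        best = c
                if best > U_i:
                    continue
                visit(nr, new, t + 1)

        visit(rng, row, 0)

    phase(0, index.full_range(), 0, 0)


def approximate_match(
    index: BidirectionalIndex,
    P: str,
    K: int,
    scheme: Scheme | None = None,
) -> list[FMOccurrence]:
    """All occurrences ``O`` of ``P`` in ``T`` with ``ED(O, P) <= K``.

    Occurrence strings are built from A/C/G/T extensions only, so they never
    contain a separator.  The same occurrence reached through several
    searches or alignments is reported once, at its minimal edit distance.
    """
    if not (0 <= K <= MAX_K):
        raise ValueError(f"unsupported edit distance K={K}; supported: 0..{MAX_K}")
    if scheme is None:
        scheme = pigeonhole_scheme(K)
    ok, uncovered = validate_scheme(scheme, K)
    if not ok:
        raise SchemeError(f"scheme does not cover {uncovered[:3]} ...")
    parts = partition_pattern(P, scheme.p)
    out: dict[tuple[int, int, int], tuple[int, BidirectionalRange]] = {}
    for search in scheme.searches:
        _run_search(index, _phase_plan(search, parts), K, out)
    occs = [
        FMOccurrence(range=rng, length=length, edit_distance=ed)
        for (b, e, length), (ed, rng) in out.items()
    ]
    occs.sort(key=lambda o: (o.range.b, o.length))
    return occs


def occurrence_string(index: BidirectionalIndex, occ: FMOccurrence) -> str:
    """Spell ``O = T[SA[b], SA[b] + length[``."""
    start = index.sa_value(occ.range.b)
    return index.text.T[start : start + occ.length]
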