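# Methods

## Text model and alphabet

The pan-genome is the concatenation `T` of `S` DNA sequences separated by
`%` and terminated by a single `$`, over the ordered alphabet
`$ < % < A < C < G < T`.  The sentinel being smallest and the separator
second-smallest guarantees that the `S` suffixes starting at separator
positions occupy the first `S` rows of the suffix array — the rows that mark
the per-sequence end nodes.  All coordinates are 0-based, half-open.  `N`
bases in input FASTA are replaced by a seeded pseudo-random nucleotide; the
seed is recorded in the index metadata so a rebuild is reproducible.

## Bidirectional FM-index

Both `T` and its full reversal `T^r` (sentinel included) are indexed.  A
partial match is a pair of synchronized half-open row intervals, `[b, e[`
over `SA` and `[b_r, e_r[` over `SA^r`, always of equal size; prepending or
appending one character costs a constant number of rank queries.

Two deliberate numerical choices:

* **Rotation semantics.**  Matching is implemented purely through LF-type
  character extensions, never by direct suffix comparison.  Sorting suffixes
  of a `$`-terminated text equals sorting its rotations, so a pattern that
  runs over the sentinel wraps around to the start of the text.  DNA
  patterns are unaffected (a wrap would cross `$`), and the graph layer gets
  the cyclically extended rightmost k-mers of end nodes for free: the
  "k-mer" `$CT` of the worked example matches exactly at the sentinel
  rotation row.
* **Suffix sorting** uses numpy prefix doubling, `O(n log^2 n)` — entirely
  adequate at the scales this reference implementation targets (up to a few
  hundred kilobases); the semi-external construction pipelines used for
  human-scale pan-genomes are out of scope here.

Parameters: `s_sa` (default 16) keeps every 16th suffix-array value, with a
marker bit vector; a located row walks at most `s_sa − 1` LF steps.  One
factor serves both directions.  Rank support stores the full per-position
occurrence table by default (`rank_block=1`); a block-sampled variant is
available and semantically identical — at Python desk scale the full table
is the faster and simpler choice, and rank engineering is an implementation
detail, not semantics.

## Graph definition

Nodes are unitigs of the k-mer de Bruijn graph of `T`; k-mers containing a
separator anywhere but their last position are excluded.  Chains break at

1. branching (a node with ≠ 1 distinct successor, or a successor with ≠ 1
   distinct predecessor),
2. separator-final k-mers (no successor window exists), and
3. **each sequence's first k-mer.**  This third rule matters: a
   sequence-start k-mer occurs without a valid predecessor window, so its
   occurrence count can exceed the multiplicity of a unitig it would
   otherwise sit inside.  Every k-mer interior to a node then occurs exactly
   `mult` times, all occurrences preceded by the same character — the
   property that makes the marker-bit walk (below) stay inside its node and
   makes `mult` equal the node's SA-interval size.  These are the "start
   node" exceptions to the in-degree = out-degree = `mult` rule.

**End nodes.**  Each sequence contributes its own end node — the unitig
ending in its separator — even when several sequences end with the same
string.  An end node's rightmost k-mer is the cyclic window starting at its
separator (its offset is recorded as `len − 1`), so the first `S` bits of
`B` mark the end nodes.  Equal-string end nodes share the SA interval of
their string; on the reverse side the shared interval's top rows are
assigned one per node (lowest id at the lowest marked row), and navigation
that enters such a group by sequence content alone returns the lowest-id
representative — the members are indistinguishable by string, which is the
most an implicit representation can observe.  The wrap edges *leaving* end
nodes (through `$` back to the text start, or through `%` into the next
sequence) are navigable but excluded from subgraph traversal and export by
default.

**Canonical node ids.**  Ids are deterministic: nodes with multiplicity ≥ 2
first, then the remaining non-end nodes, each ordered by the SA row of their
rightmost-k-mer mark; the `S` end nodes come last, ordered by their
separator row.  This ordering reproduces the published worked example's node
table exactly; any consistent relabeling would serve equally.

## Checkpoints and k-mer lookup

`B` marks, per node, the lexicographically largest row of its rightmost
k-mer, plus the in-node k-mers at offsets `0, s_cp, 2·s_cp, …` strictly
below `len − k` (checkpoints).  Lookup of an arbitrary k-mer starts at the
last row of its interval and LF-steps leftwards until a marked row; the
queried offset is the stored offset plus the number of steps, at most
`s_cp − 1` of them.

The walk is correct precisely because every in-node shift preserves the
"largest row of its interval" property (uniform multiplicity, above), and
because offset 0 is always marked: without an offset-0 mark the walk would
cross the node's left boundary and silently identify a predecessor.  For
this reason `s_cp = ∞` here means *only* the offset-0 checkpoint is kept
(the `j = 0` term of the offset rule), giving correct lookup at
`O(node length)` cost; `s_cp = None` builds the bare baseline with no
checkpoints at all, in which case arbitrary-k-mer lookup raises once it
detects an offset outside the landing node rather than return a wrong
answer.  Separator-final k-mers resolve through the reverse side when they
constitute a whole length-k end node, and through the ordinary walk
otherwise.  Default `s_cp = 128`, the recommended time/space balance; the
default `k` is 25.

## Search schemes and matching

A search `(π, L, U)` processes the `p` contiguous pattern parts in an order
that always extends the matched span left or right, with cumulative error
bounds after each part.  A scheme is valid when every error vector summing
to ≤ K is covered; validation enumerates the vectors directly.  Built in:
pigeonhole schemes for K ≤ 4 (part `i` anchored exactly, then leftward to
part 0, then rightward) and the three-search two-error scheme with
tightened bounds; other schemes (e.g. published four-error designs) load
from a text file (`p K` header, one `π L U` digit-triplet line per search)
and are validated on load.

Execution keeps one banded dynamic-programming matrix per part (band
`2K + 1`), anchored where the part's processing starts; occurrence
characters come from A/C/G/T index extensions (occurrences therefore never
contain separators).  At a part boundary every admissible state — each
(consumed occurrence length, cumulative cost) with cost in `[L_i, U_i]` —
spawns the next part; a branch dies when all band cells exceed `U_i` or the
interval empties.  Correctness rests on two facts: edit distance decomposes
at part boundaries (`ED(XY, O) = min over splits O = O₁O₂ of ED(X, O₁) +
ED(Y, O₂)`), and the covering search for the optimal decomposition's error
vector explores exactly that derivation.  Hence every occurrence within K
is found, and the minimum over derivations equals its true edit distance.
Identical occurrences reached by several searches or alignments are merged
by their interval and length.  Uniform partitioning (remainder to the left
parts) is used; scheme validity is partition-independent.

**Pattern partition vs. k**: parts shorter than ~8 characters make the
anchor phase unselective in small texts; with the supported `K ≤ 4` and
typical read lengths ≥ 50 this does not arise.

## Occurrences, loci, and redundancy

Each FM occurrence (interval pair, length, distance) expands to one text
occurrence per suffix-array row.  Two occurrences of the same query and
strand belong to the same locus when their text intervals overlap; the
filter ranks candidates by (distance, longer length, smaller start) and
keeps them greedily if disjoint from everything already kept.  This
concretizes "filtering text occurrences", which the source material leaves
unspecified; the brute-force oracle in the test suite applies the identical
rule, so the losslessness comparison is exact, and the filter is idempotent.
Queries are matched as given and as reverse complement; strands are
reported separately and filtered separately.

Occurrences of length ≥ k map to a unique node path: the leftmost k-mer is
resolved once, then each following node is reached by jumping to the node
end and taking the successor edge labelled with the next occurrence
character.  Shorter occurrences are extended to every existing k-window
(left extensions A/C/G/T; the final right extension may be a separator);
each window resolves to a node and the start offset of the occurrence
within it, deduplicated.

## Neighbor-variant scan

Given a reference node walk (e.g. a gene of the reference strain), its
depth-1 off-path neighbors are candidate linked variants when (1) a
reference coordinate can be assigned within `max_back_steps` predecessor
jumps — "unambiguously positioned" is concretized as *a predecessor whose
substring occurs exactly once in the reference sequence*, the coordinate
being that occurrence plus the spelled distance walked — (2) the strains
passing through the candidate are a subset of one marker's carriers, and
(3) the candidate's multiplicity is at least `min_mult` (default 2).
Backtracking follows each node's edge 0; with `min_mult ≥ 2` candidates sit
in low-complexity neighborhoods where this deterministic choice is
representative.  This is a screening tool: it flags candidate loci, it does
not call or annotate variants.

## Synthetic data

The generator emulates a small clonal strain collection: strain 0 is a
uniform random genome; the others apply seeded substitutions (default rate
5·10⁻³) and 1–3 bp indels (5·10⁻⁴) — magnitudes typical of closely related
bacterial isolates, where graph bubbles stay local.  Mutations avoid the
first and last `k_guard` bases so planted truth loci never interact with
sequence-end bookkeeping; a corollary is that strains share their terminal
k bases, which deliberately exercises the equal-string end-node machinery.
Reads are sampled uniformly with at most `planted_errors` edits and their
true locus recorded.  What it does *not* emulate: realistic error profiles,
coverage biases, rearrangements, horizontal transfer, or reverse-strand
sampling — passing tests demonstrate algorithmic correctness of the index
and graph operations, not robustness to real sequencing artifacts.

## Problem sizes used in validation

The validation suite runs: worked-example fidelity on the 20-character
two-strain text; exhaustive k-mer/navigation/ball equivalence against an
explicitly enumerated networkx graph on three ~3.6 kb three-strain
pan-genomes for `k ∈ {5, 11, 21}` and `s_cp ∈ {1, 2, 8, ∞}`; and
losslessness on 50 seeded pan-genomes (2–5 strains, 5–20 kb total, 100
reads of 60 bp each, each genome exercising one `K ∈ {0..4}`) against a
vectorized banded scan of the full text.  These sizes keep the whole suite
in a few minutes while covering every k-mer and every error budget at least
an order of magnitude beyond the worked example.

## Known limitations

* `K ≤ 4`; no gapped or clipped alignment, no SAM output, no paired-end
  logic, no mapping qualities.
* The index grows linearly with total sequence content (no run-length or
  r-index compression); the implementation is single-threaded Python and
  intended for method study and moderate inputs, not human-scale
  pan-genomes.
* Arbitrary-k-mer lookup on a baseline build (`s_cp=None`) raises for
  non-extreme k-mers by design.
* Equal-string end nodes are canonicalized on lookup (see above).
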