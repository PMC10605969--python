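# ccdbg — an implicit pan-genome de Bruijn graph on a bidirectional FM-index

`ccdbg` indexes a pan-genome — a collection of related genomes, e.g. strains
of one bacterial species — as a single text and represents its **colored
compacted de Bruijn graph (ccdBG) implicitly**: no nodes or edges are ever
materialized.  A bidirectional FM-index of the concatenated sequences, one
node attribute table, two marker bit vectors over suffix-array rows and two
small id maps are enough to

* navigate the graph in **O(1) per step**, forwards and backwards,
* resolve *any* k-mer to its node and offset in **O(s_cp)** via checkpoint
  k-mers,
* extract and export **symmetric subgraphs** (DOT / GFA 1.0 / TSV) around
  nodes of interest,
* perform **lossless approximate read matching** with search schemes: *every*
  occurrence within edit distance `K ≤ 4` is reported, at its minimal edit
  distance, both as a node path in the graph and as coordinates in the
  input sequences.

It is aimed at people analyzing strain collections who want exhaustive
(rather than heuristic, seed-and-extend) alignment plus graph-topological
context — e.g. scanning the neighborhood of a resistance locus for linked
variants.

## The data structure in one paragraph

The input sequences are concatenated with `%` separators and a final `$`
sentinel (alphabet order `$ < % < A < C < G < T`).  Graph nodes are unitigs
(maximal non-branching chains of k-mers; k-mers with a separator anywhere but
their last position are excluded).  Each node stores `len`, `mult` (its
occurrence count), `left_kmer` (left bound of the SA interval of its leftmost
k-mer) and `right_kmer_r` (left bound of the reverse-SA interval of its
reversed rightmost k-mer), so its substring is `T[SA[left_kmer],
SA[left_kmer]+len[`.  Bit vector `B` marks, per node, the lexicographically
largest suffix-array row of its rightmost k-mer, plus every `s_cp`-th in-node
k-mer (*checkpoints*); `IDmap` translates bit ranks into `(node id, offset)`.
`B_r`/`IDmap_r` mirror this for leftmost k-mers over the reversed text.  A
rank on `B` after one FM extension yields neighbor nodes; an LF walk of at
most `s_cp − 1` steps resolves an arbitrary k-mer.  Colors (which strains a
node occurs in) are derived on demand by locating the node's SA interval.

Search schemes `(π, L, U)` drive the approximate matching: the pattern is cut
into `p` parts, each search processes the parts in a connectivity-respecting
order with cumulative error bounds, and a scheme covering every distribution
of ≤ K errors makes the procedure lossless.  Both the pigeonhole schemes
(K ≤ 4) and the three-search two-error scheme with tightened bounds are
built in; arbitrary schemes load from a small text format.

## Worked example

The toy pan-genome `T = "CTATGTC%ATATGTTGGTC$"` (two strains) with `k = 3`:

```pycon
>>> from ccdbg import *
>>> text = PanGenomeText.from_sequences(["CTATGTC", "ATATGTTGGTC"])
>>> index = build_index(text, s_sa=16)
>>> graph = build_graph(index, text, k=3, s_cp=2)
>>> graph.n_nodes, graph.n_checkpoints
(7, 3)
>>> node_substring(graph, index, 4)
'GTTGGT'
>>> r = index.match_exact("ATG"); (r.b, r.e, r.b_r, r.e_r)
(3, 5, 9, 11)
>>> find_id_right(graph, index.match_exact("GTC").b)
0
>>> pos = find_id(graph, index, index.match_exact("TTG").b)
>>> (pos.id, pos.offset)
(4, 1)
>>> [o.edit_distance for o in approximate_match(index, "ATGTC", 1)]
[1, 0, 1, 1, 1]
```

`match_exact("ATG")` returns the synchronized interval pair `SA[3,5[` /
`SA^r[9,11[`; the k-mer `GTC` resolves to node 0 through one rank on `B`;
`TTG` is not a marked k-mer, so one LF step lands on the checkpoint `GTT`
and identifies node 4 at offset 1.  With one allowed error, `ATGTC` is found
at its exact locus plus four one-error variants — three shifted or trimmed
alignments overlapping the exact locus and one genuine one-error occurrence
in the other strain; redundancy filtering keeps one minimal-distance
occurrence per locus (two in total).

The same operations are available from the shell:

```
ccdbg synth toy --seed 7 --length 5000 --strains 3
ccdbg build toy.fasta idx -k 21
ccdbg align idx toy.reads.fastq -K 2 -o hits.tsv
ccdbg subgraph idx --seeds GATTACAGATTACAGATTACA --depth 2 --format gfa1
```

`align` writes one TSV row per text occurrence: query, strand, sequence
name, start, length, edit distance, node path and start offset in the first
node.

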