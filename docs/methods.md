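# Methods

## Model

`levelasm` is a de Bruijn–style de novo assembler for short paired-end
RNA-Seq reads whose defining output is a per-contig label describing the
structural ambiguity of the graph the contig was traced through. The
pipeline is: kmer counting → filtering → unitig compaction → overhang edge
placement → component extraction → strand deduplication → local-cycle
refinement → E/J/I partition → cornerstone selection → cycle tracing →
level assignment → coverage-ranked path enumeration → contig output.

The label is purely descriptive of graph structure: level-1 and level-2
graphs cannot yield chimeric paths (a single path, or one path per distinct
end node with no alternative routes), while level-3 graphs can, and their
contigs should be interpreted more cautiously. Coverage guides path choice
in level-3 graphs but does not guarantee non-chimerism.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 40 nt | kmer length; large enough that chance kmer collisions between unrelated gene families are negligible, small enough for 200-nt reads to contribute ~160 windows each |
| `max_overhang` | 5 nt | maximal number of overhanging bases for an edge; boundary windows must agree over the remaining k−d bases |
| `low_complexity_fraction` | 0.8 | a kmer is dropped when one nucleotide type exceeds this fraction (strictly); at the 0.800 boundary the kmer is kept |
| `paths_per_start` | 10 | complete paths traced per start node before enumeration stops |
| `contigs_per_graph` | 3 (max 5) | coverage-ranked paths emitted per level-2/3 graph; level-1 graphs always emit exactly one |
| `min_contig_len` | 200 nt | output length cutoff |

## Strand handling

Read pairs arrive in both orientations (mate 2 is the reverse complement
of the fragment's 3′ end), so kmers are counted from each read *and* its
reverse complement. This makes every connected component appear twice,
once per strand; mirror components are detected by a strand-canonical
signature over node sequences and one orientation is kept — the one whose
highest-frequency node sequence is lexicographically ≤ its reverse
complement (deterministic, content-only). Contigs are therefore reported
in an arbitrary but reproducible strand; round-trip comparisons accept a
template or its reverse complement.

## Coverage bookkeeping

A composite node built from the kmer chain w₀…w_{m−1} stores, at position
*i* < m, the count of wᵢ, and the last kmer's count at the trailing k−1
positions. Reconstruction of a path concatenates node sequences, appending
only the d novel bases across each edge, and concatenates the per-base
coverage vectors the same way; a path's rank is the plain mean of that
concatenated vector. Mean per-base coverage was preferred over mean node
frequency because it weights long and short nodes by the sequence they
actually contribute.

## Classification details

After refinement, nodes are partitioned by undirected degree (1 → E,
&gt;2 → J, else I). The cornerstone is the highest-frequency interior node
whose removal leaves exactly two connected sub-graphs; candidates whose
removal leaves one (a circumventing path exists) or more than two pieces
are skipped, ties broken by lexicographic sequence then node id. The E-set
members of the smaller sub-graph form E1, the larger's form E2 (equal
sizes: the side holding the smallest node id is E1).

Two details were genuinely open and are resolved as follows:

* **"Cycles" include reconvergence.** Cycle tracing from E1 flags a graph
  when a walk can double back on itself (a directed cycle) *or* when some
  node is reachable along two distinct routes (a bubble). Both make path
  choice ambiguous; treating only directed cycles as "cycles" would let a
  two-bubble graph with single tip nodes pass as level 1 while four
  distinct paths exist, breaking the level-1 guarantee.
* **Traversal anchors are the directed source/sink census.** Unitig
  compaction absorbs a junction kmer into its stem, so a one-to-many
  family compacts to a stem node of degree 2 with two tip sinks: no
  degree-1 start node exists and the periphery-anchored end sets would
  label the fork level 1 with an untraversable "path". Levels 1 and 2
  therefore additionally require a unique traversal anchor — exactly one
  source (traced forward) or exactly one sink (traced against edge
  direction; the stored orientation is an arbitrary strand choice) — with
  every node reachable from it. E1/E2 are then re-anchored to the start
  and its reachable ends, which keeps the level semantics exact: level 1
  ⟺ one complete path, level 2 ⟺ one path per E2 node. Graphs with
  multiple sources *and* multiple sinks, unreachable nodes, cycles,
  reconvergence, or no cornerstone are level 3.

Singleton components (one composite node) are level 1: they are complete
unambiguous fragments. Two-node chains have an empty interior set, hence
no cornerstone, and fall to level 3 by the "all other cases" rule.

Path enumeration is depth-first with neighbours ordered by descending
representative frequency (ties: sequence, then id), each node used at most
once per path, so cyclic graphs contribute finitely many candidates. When
no complete start→end path exists, the longest partial path is emitted
alone and flagged; partial paths are used only in that case.

## The simulator

`simulate_read_pairs` emulates an error-free uniform-coverage protocol:
200-nt mates on 300-nt outer fragments ("insert size" is the outer span —
with 200-nt mates the two overlap by 100 nt; an inner-gap reading would
need 700-nt fragments and could not fit 300-nt transcripts). Pairs are
allocated to transcripts proportionally to length with largest-remainder
rounding (the requested total is met exactly) and fragment starts are
tiled evenly per transcript, so mean per-site coverage equals
2·n_pairs·read_length/Σlength both per transcript and in aggregate; a
uniform-random start mode exists for robustness testing. Transcripts
shorter than the fragment span are covered with the span truncated, never
skipped.

What the simulator deliberately omits: sequencing error, quality-score
variation, expression heterogeneity, intron/isoform structure and library
artefacts. Passing round-trip tests therefore demonstrates the
correctness of the graph algorithms under clean conditions, not robustness
to real-data noise — on real libraries, error kmers fragment and tangle
graphs, and the level distribution will shift toward level 3.

The toy generators produce minimal families realising each graph
archetype: unrelated transcripts (level 1), shared 5′ regions (level 2),
shared interior blocks, two-SNP haplotype pairs (two bubbles in sequence,
four paths) and exact internal repeats (directed cycles) — all level 3.
The chimeric-reference generator splices random two-parent breakpoints,
preserving record counts and recording parent ids.

## Problem sizes and numerics

The test and acceptance runs use deliberately compact instances chosen as
desk-scale study conditions: toy families at k = 15 with 100-nt reads;
round-trip identity on 50 random transcripts of 300–5000 nt at 30×
coverage with the default k = 40; oracle equivalence on 200 random graphs
of ≤ 30 nodes; and a 500-transcript mixture (300–800 nt, 20% of
transcripts in two-member shared-sequence families, ~15× coverage) for the
level-distribution analogue. All randomness flows through explicit integer
seeds; assembly itself is deterministic, with every ordering given a total
tie-break (count, then sequence, then id). Composite-node boundaries reuse
exact string comparison only — there is no approximate matching anywhere.

## Known limitations

* Kmer counting is an in-memory dictionary; multi-gigabase read sets would
  need disk-backed or probabilistic counting, which is out of scope.
* No error correction: a single sequencing error produces up to k spurious
  kmers and can split or tangle a component.
* Paired-end insert-size information is not used for scaffolding; mates
  contribute kmers independently.
* Level 3 is a single catch-all; sub-scoring its graphs by start/end/cycle
  counts is future work.
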