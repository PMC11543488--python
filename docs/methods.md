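# Methods

This note records what `graphasm` computes, the assumptions behind each
stage, the defaults and why, and what the closed-loop tests do and do not
demonstrate.

## Assembly graph and GFA dialect

A graph vertex is an *oriented* read; when a GFA file references a segment
in both orientations, each (read, orientation) pair becomes a distinct
node, and no dual-graph (reverse-complement symmetry) constraint is
enforced.  Edges are suffix→prefix overlaps.  The overlap length of an L
line is the source-consumed length of its CIGAR (M, =, X and I consume the
source; D does not; other operators are rejected).  Edges whose overlap is
not strictly shorter than both incident reads are dropped at load with a
warning rather than failing the whole file, since real graph dumps
occasionally contain contained-read artifacts.  Coordinates are 0-based,
half-open throughout.  Scores round-trip through a `ps:f` tag and labels
through `gt:i` on L lines.

## Read simulation and what it stands in for

The simulator replaces an external read simulator and assembler so the
whole loop is hermetic.  Its genome is uniform-random sequence with
planted *exact* multi-copy repeat families: `repeat_copies` identical
units of `repeat_unit_length` bp, placed without overlap until copies
occupy `repeat_fraction` of the genome.  Defaults — 30% repeat content in
2 kb units, 10 copies per family — emulate a dispersed high-identity
transposon-like family; real mammalian genomes carry comparable or higher
interspersed-repeat fractions.  Reads are truncated-normal in length,
uniform in start, with i.i.d. substitution/insertion/deletion errors in
equal proportion (default rate 0.001, matching the ≥99.9% accuracy of HiFi
reads; default length 15 kb / sd 3 kb at full scale).  Each read records
its true interval and strand before error injection.

The overlap graph is built from true coordinates: a directed edge u→v for
every same-strand pair with `start(u) < start(v) < end(u) < end(v)` and
overlap `end(u) − start(v) ≥ min_overlap` (default 500 bp).  Containments
produce no edge.  When repeat annotations are supplied, the builder also
emits *sequence-implied* edges between reads in different copies of a
family, by translating coordinates through the copy equivalence and
applying the same dovetail test.  These edges have exactly matching
overlap sequences (the copies are identical) but are positionally false —
the ambiguity a sequence-overlap assembler necessarily introduces, and the
negative class the scorer must learn.  Without them, a coordinate-built
graph contains almost no incorrect edges and edge classification is
degenerate.

What the simulator does **not** model: diploidy/heterozygosity, diverged
(non-identical) repeat copies, chimeric reads, coverage waves, and
realistic HiFi quality/pass-number profiles.  Passing tests therefore
demonstrate correctness of the machinery and learnability of
repeat-induced ambiguity under idealized conditions, not performance on
real data.

## Ground-truth labels

Edge labels are positional.  Retention keeps exactly the true dovetail
edges.  Tip removal then runs per component: seed at the unvisited node
with the lowest read start (ties by read id), BFS forward over retained
edges, then BFS backward (against edge direction) from the visited node
with the highest read *end* coordinate ("highest position" is read as
highest end; a config switch selects highest start instead).  Edges
traversed in both sweeps are positive; all others — one-sweep, unreached,
or non-retained — are negative.  Reseeding among still-unvisited nodes
guarantees every edge is labeled and the loop terminates.

## Model

Features: node = (out-degree, in-degree), unscaled by default (an optional
z-score switch exists); edge = (overlap length, overlap similarity).
Overlap similarity compares the exact suffix/prefix windows of length
`overlap_length` under global (NW) alignment; similarity is clamped at 0
so noisy edges stay in [0, 1].  Both matrices pass a three-layer ReLU MLP
to width d.

Positional encodings are the k smallest nontrivial eigenvectors of the
symmetric normalized Laplacian of the undirected graph (k = 16 by
default), linearly projected to width d and added to the node embedding.
Eigenvector signs are fixed deterministically at inference (largest-
magnitude entry positive) and flipped uniformly at random per column
during training, the standard augmentation against sign ambiguity.  On
graphs with fewer than k+1 nodes the encoding is truncated and
zero-padded.

Attention is directed: each node attends over its in-neighbors, with no
symmetrization.  The per-head edge gate multiplies the scaled query–key
product elementwise (an additive variant is available behind a config
flag for ablation).  Attention logits are clamped to ±5 before the
softmax; the clamp bound is configurable.  A node with no in-neighbors
receives a zero attention update, so the residual passes its input
through unchanged into the norm/FFN path.  Norm is batch normalization
(running statistics in eval mode).  The score head is a three-layer MLP
(3d → 64 → 32 → 1) with a sigmoid; its final logit is additionally
bounded to ±30 so scores are strictly inside (0, 1) in float64 even for
untrained parameters.

Defaults left open by the architecture and fixed here: L = 4 layers,
H = 8 heads, d = 64, k = 16.  All are config-exposed.

## Training

Binary edge classification with class-weighted BCE: mean over edges of
`−[w·y·log p + (1−y)·log(1−p)]`, with `w = negatives/positives` computed
on the training labels (uniform weighting if a class is absent);
predictions are clipped 1e-7 from the boundary.  Adam at learning rate
1e-4.  Graphs are partitioned into node-disjoint subgraphs — METIS when
the pymetis bindings are importable, otherwise a seeded synchronized-BFS
region growing with the identical contract — and cross-partition edges
are dropped from the loss (their count is logged).  One optimizer step
per subgraph per epoch; defaults 50 epochs with early-stopping patience
10 on validation loss; the best-validation parameters are restored.
Everything is seeded and bit-reproducible.

## Decoding

"Randomly select the N highest-probability edges" is implemented as a
deterministic top-N by score with a seeded random key breaking exact
score ties (the only reading satisfying both "random" and "highest").
Each seed edge is extended greedily forward from its head and backward
from its tail, always taking the highest-scoring admissible edge (ties:
lowest edge id), skipping visited nodes.  Candidates within an iteration
may overlap; only the winner — longest implied contig — marks its nodes
visited.  Iteration stops when the best candidate has fewer than
`min_path_reads` reads (default 3); N defaults to 16.  Greedy extension
has no score threshold, so once high-scoring continuations are exhausted
a walk can cross low-scoring edges; on repeat-containing graphs this
trades contiguity against misassemblies exactly as the scores dictate.

## Evaluation

Contigs are aligned to the known reference by exact k-mer anchoring
(k = 31, sampled every 8 bp) chained on a common diagonal within a 100 bp
band; each discordant junction between consecutive blocks of a contig
(diagonal jump > 1 kb or backward step) counts one misassembly — a
deliberately simplified version of QUAST's taxonomy.  NA50 uses the total
assembly length as denominator, NGA50 the reference length, both as "the
shortest block at which the sorted blocks reach half the denominator".
Genome fraction is the percent of reference bases covered by the union of
block intervals.  Exact k-mer anchoring is adequate at the package's
error rates (≤0.1%, one error per ~1 kb ≫ k); it would undercount
alignable bases for diverged sequence.

## Problem sizes

The closed-loop experiments run at desk scale: oracle decoding on a
100 kb genome at 20× (about 500 reads, 4 kb mean length), and label
recovery with a d=64, 2-layer, 4-head model on five 50 kb training and
two validation graphs at 15× (about 190 nodes and 2 500 edges each,
including repeat-induced false edges).  Read lengths are scaled to genome
size so that graphs keep realistic overlap depth.  At these sizes the
full test suite and the acceptance script each complete in about a
minute on one CPU.

## Known limitations

- The scorer sees no sequence content (k-mer profiles etc.); features are
  purely topological plus overlap statistics.
- Exact repeat copies make overlap similarity uninformative for the
  false-edge class; diverged repeats would give the model an easier and
  more realistic signal.
- Batch-norm statistics tie the model mildly to the training graph scale.
- The greedy search is myopic; no look-ahead or beam variant is provided.
- Reverse-complement duality is not enforced: '-' nodes are independent
  vertices, and the simulator emits forward-strand reads by default.
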