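# Methods

## Problem and guarantee

The package answers subgraph queries over a database of undirected,
simple, vertex- and edge-labeled graphs: return exactly the graphs
containing the query under **non-induced** subgraph isomorphism with
equal vertex and edge labels (the standard semantics for substructure
search; induced matching is out of scope). The architecture is
filter-and-verify. Filters may keep non-answers but must never discard a
true answer; the exact matcher then removes the remaining false
positives, so the pipeline's answer set equals brute-force verification
by construction *if* the filters are no-false-negative. That property is
what most of the test suite and the acceptance script measure.

## Codes and why dominance holds

For a vertex *v*, the code quadruple is (L, AE, Laps, nWalk); for a
graph, the counter components are element-wise sums over vertices plus
the rank-wise sorted eigenvalue sequences (Lapsseqs) and the vertex/edge
counts. Dominance under containment follows from three monotonicity
facts, each tested directly against independent oracles:

- **Counting.** An embedding maps each query vertex onto a distinct host
  vertex with the same label, each incident (edge label, neighbor label)
  pair onto a distinct host pair, and each length-W walk onto a host
  walk. Counts therefore only grow, and after hashing into counter
  strings sums still only grow — collisions merge counters and preserve
  inequality direction. This is why shrinking the counter length to 4
  (heavy collisions) must not, and measurably does not, change answers.
- **Locality.** The Level-N spanning graph of a query vertex is
  subgraph-isomorphic to the Level-N spanning graph of its image: a path
  of length ≤ N in the query maps to one in the host, and induced edges
  are preserved. The local graph is computed as the BFS ball of radius N
  with all internal edges (walk distance ≤ N equals shortest-path
  distance ≤ N).
- **Interlacing.** For H ⊆ G, the sorted Laplacian eigenvalues satisfy
  λ_i(H) ≤ λ_i(G) at equal rank (padding H with isolated vertices adds
  zero eigenvalues, and adding edges to a graph can only raise each
  eigenvalue of D − A). This makes both the per-vertex spectra and the
  per-rank graph sequences comparable by element-wise dominance.

Two deliberate key choices in the hashed features: the AE key is the
ordered pair (edge label, neighbor vertex label) — the center vertex's
own label is excluded, since label equality is enforced separately — and
the walk key is the **terminal-vertex label only**. Recording interior
walk content would sharpen the filter slightly but walks are used
precisely because powers of the adjacency matrix make them cheap;
per-terminal-label grouping keeps the monotonicity argument elementary.
Closed walks (the diagonal of A^W) are counted: a walk returning to a
start vertex of label *l* is a walk to a vertex of label *l*.

The vertex filter compares raw labels directly rather than hashed L
counters, making the label-equality condition exact and immune to
collisions at any counter length; the hashed L counter still exists
because graph-level sums need it.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| N (`level_n`) | 2 | spanning-graph radius; larger N tightens the filter but each vertex's eigendecomposition grows with the ball, and past 2–3 levels the candidate-set reduction flattens |
| W (`walk_len`) | 2 | walk length; A^W is computed by exact integer matrix products, so small W keeps counts cheap and overflow-free |
| t (`n_eigen`) | 3 | eigenvalues kept per vertex; spectra of balls smaller than t are zero-padded (consistent with the isolated-vertex padding used in the interlacing argument) |
| S (`code_len_*`) | 30 | counter-string length for L, AE, nWalk; correctness is independent of S (collisions are safe), S trades index size against filter power |
| k (`bits_per_item`) | 1 | counter positions per hashed item; k > 1 is supported since dominance survives superposition |
| m, M | 2, 8 | signature-tree fan-out bounds |
| eps | 1e-8 | slack on every spectral comparison, applied only on the non-pruning side so eigensolver round-off can cause false positives, never false negatives |

The hash is a seeded 64-bit FNV-1a over the serialized item with a
splitmix-style finalizer, iterated with a round counter until k distinct
positions emerge — deterministic across runs and platforms, which the
byte-level determinism checks rely on. Any uniform deterministic hash
would do; uniformity is verified by a chi-square test.

## Index

The LnGCode-Tree stores only the (L, AE, nWalk) triples; the spectral
sequences stay in a flat per-graph code store and are applied as a
post-traversal scan, keeping tree nodes small. Leaves group graphs with
identical triples; an internal node's code is the **element-wise
maximum** of its children — the counter generalization of signature-tree
bit-OR, and the minimal combiner for which "child dominated ⇒ subtree
not pruned" holds. Because leaf codes are exact and internal maxima are
tight, traversal returns *exactly* the linear-scan dominance set, which
the tests assert rather than assume.

Insertion descends to the bottom level choosing the child needing least
total counter enlargement (ties: smaller code mass, then child order);
overflowing nodes split with a deterministic quadratic-style heuristic
(seeds = the pair of entries at maximal L1 distance, remaining entries
to the seed needing least enlargement, ties to the smaller group, with
forced assignment to respect the minimum fan-out). Splits propagate
upward and the height grows only at the root, so all leaves stay at
equal depth. Deletion is lazy: ids are removed from their leaf, empty
nodes are unlinked, ancestor codes are recomputed exactly (they may
shrink), and a single-child root is collapsed; nodes may underflow below
m. Query correctness is oracle-checked independently of tree shape, so
the lazy policy costs only filter speed, never answers.

The index persists to a single file: magic + format version, a JSON
header (coding configuration, fan-out bounds, graph count), fixed-width
little-endian int64 counters and float64 spectra per graph, then the
tree topology in preorder. Loading rebuilds internal codes bottom-up;
save→load→save is byte-identical.

## Verification

The in-repo matcher is a VF2-style backtracking search: query vertices
are ordered deterministically (most already-mapped neighbors, then
descending degree, then id), candidate images must match the vertex
label, have sufficient degree, lie in the candidate vertex set when one
is supplied, and be consistent with every mapped neighbor (host edge
present with equal label). Existence suffices for the query problem;
embeddings are enumerated only on request, one at a time.

## Synthetic data

The generator emulates the shape of the classic transactional-graph
benchmarks: per graph an edge count drawn Poisson around the target mean
(min 1), the vertex count chosen as the smallest n with n(n−1)/2 ≥
e/density so the realized density 2e/(n(n−1)) tracks the target, edges
sampled uniformly without replacement, labels uniform over the
alphabets. "Graph size" is read as *edge count*, matching the
edge-counted query sets used with such benchmarks. Defaults (10 000
graphs, 30 edges, density 0.5, 50-symbol alphabets) mirror the common
benchmark configuration; the test and acceptance workloads scale this
to desk size (200–1000 graphs, 8–15 edges, 3–5 labels — small alphabets
deliberately create label collisions and hence non-trivial filtering).
Connectivity is patched with minimal random-label bridging edges so
query extraction always succeeds; this biases the edge-count mean
upward by well under one edge at the default densities, which the
generator's moment test accounts for.

Queries are grown by randomized edge-BFS from a random edge of a random
eligible graph, giving connected queries with an exact edge count and a
guaranteed (planted) source answer. `plant_query` embeds a given query
into a freshly decorated host with a known ground-truth mapping — the
harness behind every dominance property test.

What the generator does **not** emulate: the degree distributions,
ring/fragment structure and label frequencies of real chemical
compounds, correlated label patterns, or repeated frequent substructures
across graphs. Passing tests therefore demonstrate correctness of the
filtering contract and index semantics on uniform random workloads, not
the candidate-set sizes or timings one would measure on real compound
libraries; filter *power* (though not correctness) on real data will
differ.

## Numerical choices and degenerate inputs

Eigenvalues come from the dense symmetric eigensolver; all spectral
comparisons carry eps = 1e-8 on the safe side, and negatives within
1e-9 of zero are clamped. Walk counts use exact integer arithmetic (no
floating-point matrix powers). Empty databases, edgeless graphs,
isolated vertices and disconnected database or query graphs are all
legal inputs: an isolated vertex has an all-zero AE/nWalk code and a
singleton spanning graph, and connectedness is nowhere assumed by the
filters. Timings reported by `bench` are environment-dependent and are
excluded from every determinism check and result file.

## Known limitations

- Directed graphs, multigraphs, weighted edges and induced-subgraph
  semantics are out of scope.
- The verifier is exponential in the worst case, as any exact subgraph
  isomorphism test must be; the filters bound practice, not theory.
- Deletion never merges underflowing nodes, so heavy churn can degrade
  tree selectivity (not correctness) until a rebuild.
- The index file format is versioned but not forward-compatible.
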