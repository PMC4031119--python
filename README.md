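# lngcoding

Substructure search over databases of vertex- and edge-labeled graphs —
the core retrieval problem behind chemical-compound lookup in
cheminformatics and drug discovery: *given a query graph Q, return every
database graph G that contains Q* under non-induced subgraph isomorphism
with matching vertex and edge labels.

Subgraph isomorphism is NP-complete, so testing the query against every
graph is hopeless at database scale. `lngcoding` implements a
**filter-and-verify** method with a *no-false-negative* guarantee: cheap
numeric codes prune graphs that provably cannot contain the query, and
only the survivors are handed to an exact matcher.

## Method

Every vertex *v* of a graph is summarized by a code quadruple
**(L(v), AE(v), Laps(v), nWalk(v))**:

- **L(v)** — a counter string (fixed-length array of non-negative
  counters) with the hashed vertex label set to 1;
- **AE(v)** — a counter string summing, over the edges incident to *v*,
  the hash of the pair *(edge label, neighbor label)*;
- **Laps(v)** — the *t* largest eigenvalues of the Laplacian **D − A** of
  the *Level-N spanning graph* of *v* (the subgraph induced on all
  vertices within walk distance N of *v*);
- **nWalk(v)** — a counter string accumulating, per terminal-vertex
  label, the number of length-W walks from *v* (entries of the row of
  **A**^W).

The graph code sums the counter components element-wise over all vertices
and keeps, per eigenvalue rank *r* ≤ *t*, the sequence of rank-*r* vertex
eigenvalues sorted non-ascending (*Lapsseqs*). If Q ⊆ G then every
component of Q's code is element-wise dominated by G's: label and walk
counts can only grow, and Laplacian eigenvalues interlace —
λ<sub>i</sub>(H) ≤ λ<sub>i</sub>(G) for any subgraph H at equal rank.
Hash collisions merge counters and therefore never break dominance, so
filtering is correct at any code length.

Queries run in three stages:

1. **Graph filter** — traverse the *LnGCode-Tree*, a balanced signature
   tree whose leaves group graphs with identical (L, AE, nWalk) codes and
   whose internal nodes carry element-wise maxima of their children; a
   subtree is pruned when any counter falls below the query's. Survivors
   are scanned against the stored Lapsseqs and size counts.
2. **Vertex filter** — each query vertex gets a candidate set of
   database-graph vertices with equal label and dominated AE / Laps /
   nWalk codes; any empty set removes the graph.
3. **Verification** — a VF2-style backtracking matcher, seeded with the
   candidate vertex sets, decides containment exactly.

Default parameters: spanning-graph level **N = 2**, walk length
**W = 2**, **t = 3** eigenvalues, counter length **30**. See
`docs/methods.md` for the rationale and the numerical choices.

## Worked example

Graphs are exchanged in the line-oriented transactional text format
(`t # <id>` / `v <id> <label>` / `e <u> <v> <label>`). Generate a
synthetic database plus a query set extracted from it, build the index,
and run the pipeline:

```sh
lngcoding generate --db demo-db.gsp --queries demo-q.gsp \
    --n-graphs 100 --avg-edges 12 --density 0.4 \
    --vertex-labels 5 --edge-labels 3 \
    --n-queries 5 --query-edges 4-8 --seed 42
lngcoding index --db demo-db.gsp --index demo.idx
lngcoding query --index demo.idx --db demo-db.gsp \
    --queries demo-q.gsp --out demo
lngcoding bench --index demo.idx --db demo-db.gsp --queries demo-q.gsp
```

The bench report prints:

```json
{
 "mean_answers": 1.0,
 "mean_candidates": 1.0,
 "mean_primary_candidates": 1.2,
 "n_database": 100,
 "n_queries": 5
}
```

Of 100 database graphs, the graph filter leaves on average 1.2 primary
candidates per query, the vertex filter tightens this to exactly the 1.0
true answers (the filters removed every false positive before
verification), and verification confirms them. `demo.tsv` lists one row
per surviving (query, graph) pair with phase flags:

```
query_id  graph_id  primary  candidate  answer
0         65        1        1          1
0         70        1        0          0
1         59        1        1          1
```

Graph 70 passed the graph-level filter for query 0 but was eliminated by
the vertex filter — a false positive caught before the expensive exact
test. `lngcoding validate` re-checks any result set against brute-force
verification of every database graph.

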