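"""Vertex and graph codes and the dominance comparisons the filters use.

A vertex code is the quadruple (L, AE, Laps, nWalk):

* ``L`` — counter string with the hashed vertex label set to 1;
* ``AE`` — counter string summing, over incident edges, the hash of the
  two-tuple (edge label, neighbor vertex label);
* ``Laps`` — the t largest Laplacian eigenvalues of the vertex's Level-N
  spanning graph;
* ``nWalk`` — counter string accumulating, per terminal vertex label, the
  number of length-W walks starting at the vertex.

A graph code combines the counter components of all vertices by
element-wise ADD, and carries per-rank sequences of the vertex
eigenvalues (Lapsseqs) plus the vertex and edge counts.  Containment of
graphs implies element-wise dominance of the codes, which is what the
filtering conditions exploit; hash collisions merge counters and so
preserve dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import CodingConfig, hash_label, laplacian_spectrum, lnsg, walk_label_counts, walk_matrix
from .graphs import LabeledGraph

__all__ = [
    "VertexCode",
    "GraphCode",
    "counter_add",
    "counter_dominates",
    "seq_dominates",
    "encode_vertex",
    "encode_graph",
]


def counter_add(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Element-wise ADD of two equal-length counter strings."""
    if a.shape != b.shape:
        raise ValueError(f"counter length mismatch: {a.shape} vs {b.shape}")
    return a + b


def counter_dominates(big: np.ndarray, small: np.ndarray) -> bool:
    """True iff ``big[j] >= small[j]`` for every position j."""
    if big.shape != small.shape:
        raise ValueError(f"counter length mismatch: {big.shape} vs {small.shape}")
    return bool(np.all(big >= small))


def seq_dominates(big_seq: np.ndarray, small_seq: np.ndarray, eps: float = 1e-8) -> bool:
    """True iff ``big_seq[i] >= small_seq[i] - eps`` over the small sequence.

    Both sequences must be non-ascending and ``len(big) >= len(small)``;
    only the first ``len(small)`` positions are compared.  ``eps`` guards
    against eigensolver round-off and is applied on the safe side (a
    borderline pair is *not* rejected).
    """
    big = np.asarray(big_seq, dtype=float)
    small = np.asarray(small_seq, dtype=float)
    for name, seq in (("big_seq", big), ("small_seq", small)):
        if seq.size > 1 and np.any(np.diff(seq) > 1e-12):
            raise ValueError(f"{name} is not non-ascending")
    if big.size < small.size:
        raise ValueError("big_seq shorter than small_seq")
    return bool(np.all(big[: small.size] >= small - eps))


@dataclass
class VertexCode:
    """Per-vertex code quadruple plus the raw label.

    The raw label is kept so the vertex filter's label-equality condition
    is exact and immune to hash collisions; the hashed L counter is still
    built because graph codes sum it.
    """

    raw_label: str
    l: np.ndarray
    ae: np.ndarray
    laps: np.ndarray
    nwalk: np.ndarray


@dataclass
class GraphCode:
    """Whole-graph code: summed counters, per-rank spectra, sizes."""

    l: np.ndarray
    ae: np.ndarray
    nwalk: np.ndarray
    lapsseqs: np.ndarray  # shape (t, n_vertices), each row non-ascending
    n_vertices: int
    n_edges: int

    def counter_triple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.l, self.ae, self.nwalk)


def encode_vertex(
    g: LabeledGraph,
    v: int,
    cfg: CodingConfig,
    _walks: np.ndarray | None = None,
) -> VertexCode:
    """Build the code quadruple for vertex ``v`` of ``g``.

    ``_walks`` may carry a precomputed ``walk_matrix(g, cfg.walk_len)`` so
    that whole-graph encoding factors the matrix power once.
    """
    if not (0 <= v < g.n):
        raise ValueError(f"vertex {v} not in graph {g.graph_id}")
    k, seed = cfg.bits_per_item, cfg.hash_seed
    label = g.vertex_labels[v]

    l_code = np.zeros(cfg.code_len_l, dtype=np.int64)
    for p in hash_label(label, cfg.code_len_l, k, seed):
        l_code[p] = 1

    ae_code = np.zeros(cfg.code_len_ae, dtype=np.int64)
    for u in g.neighbors(v):
        pair = (g.edge_label(v, u), g.vertex_labels[u])
        for p in hash_label(pair, cfg.code_len_ae, k, seed):
            ae_code[p] += 1

    laps = laplacian_spectrum(lnsg(g, v, cfg.level_n), cfg.n_eigen)

    nwalk = np.zeros(cfg.code_len_walk, dtype=np.int64)
    for lab, count in walk_label_counts(g, v, cfg.walk_len, _walks=_walks).items():
        for p in hash_label(lab, cfg.code_len_walk, k, seed):
            nwalk[p] += count

    return VertexCode(label, l_code, ae_code, laps, nwalk)


def encode_graph(g: LabeledGraph, cfg: CodingConfig) -> GraphCode:
    """Fold vertex codes into the graph code.

    The counter components are element-wise sums over all vertices;
    ``lapsseqs[r]`` is the multiset of rank-r eigenvalues over vertices,
    sorted non-ascending.
    """
    walks = walk_matrix(g, cfg.walk_len) if g.e else None
    l_code = np.zeros(cfg.code_len_l, dtype=np.int64)
    ae_code = np.zeros(cfg.code_len_ae, dtype=np.int64)
    nwalk = np.zeros(cfg.code_len_walk, dtype=np.int64)
    per_vertex_laps = np.zeros((g.n, cfg.n_eigen))
    for v in g.vertices:
        vc = encode_vertex(g, v, cfg, _walks=walks)
        l_code += vc.l
        ae_code += vc.ae
        nwalk += vc.nwalk
        per_vertex_laps[v] = vc.laps
    # rank-wise non-ascending sort over vertices
    lapsseqs = -np.sort(-per_vertex_laps, axis=0).T.copy()
    return GraphCode(l_code, ae_code, nwalk, lapsseqs, g.n, g.e)
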