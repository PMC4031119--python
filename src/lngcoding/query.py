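"""Two-step filtering and VF2 verification — the full query pipeline.

A subgraph query asks for every database graph that contains the query
under non-induced subgraph isomorphism with equal vertex and edge labels.
The pipeline is filter-and-verify:

1. traverse the LnGCode-Tree with the graph-level counter conditions,
   then scan the survivors' stored spectra (Lapsseqs) and sizes — this
   yields the *primary candidates*;
2. per primary candidate, compute candidate vertex sets with the
   vertex-level conditions; an empty set for any query vertex prunes the
   graph — survivors are the *candidates*;
3. verify each candidate with a VF2-style backtracking matcher seeded by
   the candidate vertex sets — these are the *answers*.

Both filtering conditions are no-false-negative: a contained query is
never pruned, because containment implies element-wise code dominance.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .codes import (
    GraphCode,
    VertexCode,
    counter_dominates,
    encode_graph,
    encode_vertex,
    seq_dominates,
)
from .features import CodingConfig, walk_matrix
from .graphs import LabeledGraph
from .index import LnGCodeTree

__all__ = [
    "QueryResult",
    "graph_filter",
    "vertex_filter",
    "candidate_vertex_map",
    "vf2_verify",
    "run_query",
    "brute_force_query",
]

#: default slack on spectral comparisons, applied on the non-pruning side
DEFAULT_EPS = 1e-8


@dataclass
class QueryResult:
    """Nested result sets of one query, with per-phase statistics.

    Invariant: ``answers <= candidates <= primary_candidates`` (as sets,
    all sorted ascending for determinism).
    """

    query_id: int
    primary_candidates: list[int]
    candidates: list[int]
    candidate_vertex_maps: dict[int, dict[int, list[int]]]
    answers: list[int]
    stats: dict = field(default_factory=dict)


def graph_filter(q: GraphCode, g: GraphCode, eps: float = DEFAULT_EPS) -> bool:
    """Graph-level filtering condition.

    ``g`` can contain ``q`` only if all hold: the L, AE and nWalk counters
    of ``g`` dominate ``q``'s element-wise; ``g`` has at least as many
    vertices and edges; and for every eigenvalue rank the first
    ``q.n_vertices`` entries of ``g``'s ranked spectrum dominate ``q``'s
    (within ``eps``).
    """
    if (q.l.size, q.ae.size, q.nwalk.size) != (g.l.size, g.ae.size, g.nwalk.size):
        raise ValueError("graph codes built with different configurations")
    if g.n_vertices < q.n_vertices or g.n_edges < q.n_edges:
        return False
    if not counter_dominates(g.l, q.l):
        return False
    if not counter_dominates(g.ae, q.ae):
        return False
    if not counter_dominates(g.nwalk, q.nwalk):
        return False
    for r in range(q.lapsseqs.shape[0]):
        if not seq_dominates(g.lapsseqs[r], q.lapsseqs[r], eps):
            return False
    return True


def vertex_filter(qv: VertexCode, gv: VertexCode, eps: float = DEFAULT_EPS) -> bool:
    """Vertex-level filtering condition.

    A database vertex is a candidate image of a query vertex only if the
    raw labels are equal, its AE and nWalk counters dominate the query
    vertex's, and its local spectrum dominates rank-wise (within ``eps``).
    """
    if qv.ae.size != gv.ae.size or qv.nwalk.size != gv.nwalk.size:
        raise ValueError("vertex codes built with different configurations")
    if qv.raw_label != gv.raw_label:
        return False
    if not counter_dominates(gv.ae, qv.ae):
        return False
    if not np.all(gv.laps >= qv.laps - eps):
        return False
    return counter_dominates(gv.nwalk, qv.nwalk)


def candidate_vertex_map(
    Q: LabeledGraph,
    G: LabeledGraph,
    qcodes: Sequence[VertexCode],
    gcodes: Sequence[VertexCode],
    eps: float = DEFAULT_EPS,
) -> dict[int, list[int]] | None:
    """Candidate vertex sets for every query vertex, or ``None`` to prune.

    Returns, per query vertex, the sorted list of G-vertices passing
    :func:`vertex_filter`; ``None`` signals that some query vertex has no
    candidate image, hence G cannot contain Q.
    """
    out: dict[int, list[int]] = {}
    for v in Q.vertices:
        cands = [u for u in G.vertices if vertex_filter(qcodes[v], gcodes[u], eps)]
        if not cands:
            return None
        out[v] = cands
    return out


def _query_order(Q: LabeledGraph) -> list[int]:
    """Deterministic matching order: max-degree start, then most mapped
    neighbors, ties by descending degree then ascending id."""
    if Q.n == 0:
        return []
    order: list[int] = []
    placed: set[int] = set()
    while len(order) < Q.n:
        best = None
        best_rank = None
        for v in Q.vertices:
            if v in placed:
                continue
            mapped_nbrs = sum(1 for u in Q.neighbors(v) if u in placed)
            rank = (-mapped_nbrs, -Q.degree(v), v)
            if best_rank is None or rank < best_rank:
                best, best_rank = v, rank
        assert best is not None
        order.append(best)
        placed.add(best)
    return order


def vf2_verify(
    Q: LabeledGraph,
    G: LabeledGraph,
    seed_map: Mapping[int, Sequence[int]] | None = None,
    return_embedding: bool = False,
) -> bool | tuple[bool, dict[int, int] | None]:
    """Backtracking test for non-induced, label-preserving subgraph
    isomorphism of ``Q`` into ``G``.

    Searches for an injective map of V(Q) into V(G) preserving vertex
    labels and mapping every Q-edge to a G-edge with equal label.  When
    ``seed_map`` is given, each query vertex's images are restricted to
    its candidate set.  The search order is deterministic.
    """
    if Q.n > G.n or Q.e > G.e:
        result: tuple[bool, dict[int, int] | None] = (False, None)
        return result if return_embedding else False

    order = _query_order(Q)
    domains: list[list[int]] = []
    for v in order:
        allowed = seed_map.get(v) if seed_map is not None else None
        dom = [
            u
            for u in (sorted(allowed) if allowed is not None else G.vertices)
            if G.vertex_labels[u] == Q.vertex_labels[v] and G.degree(u) >= Q.degree(v)
        ]
        if not dom:
            return (False, None) if return_embedding else False
        domains.append(dom)

    mapping: dict[int, int] = {}
    used: set[int] = set()

    def backtrack(pos: int) -> bool:
        if pos == len(order):
            return True
        v = order[pos]
        for u in domains[pos]:
            if u in used:
                continue
            ok = True
            for w in Q.neighbors(v):
                if w in mapping:
                    gu = mapping[w]
                    if not G.has_edge(u, gu) or G.edge_label(u, gu) != Q.edge_label(v, w):
                        ok = False
                        break
            if ok:
                mapping[v] = u
                used.add(u)
                if backtrack(pos + 1):
                    return True
                del mapping[v]
                used.remove(u)
        return False

    found = backtrack(0)
    if return_embedding:
        return (found, dict(mapping) if found else None)
    return found


class VertexCodeCache:
    """Lazy per-graph vertex-code cache shared across queries."""

    def __init__(self, cfg: CodingConfig):
        self.cfg = cfg
        self._store: dict[int, list[VertexCode]] = {}

    def get(self, g: LabeledGraph) -> list[VertexCode]:
        codes = self._store.get(g.graph_id)
        if codes is None:
            walks = walk_matrix(g, self.cfg.walk_len) if g.e else None
            codes = [encode_vertex(g, v, self.cfg, _walks=walks) for v in g.vertices]
            self._store[g.graph_id] = codes
        return codes


def run_query(
    index: LnGCodeTree,
    graphs: Mapping[int, LabeledGraph],
    Q: LabeledGraph,
    eps: float = DEFAULT_EPS,
    vertex_cache: VertexCodeCache | None = None,
) -> QueryResult:
    """Run the full filter-and-verify pipeline for one query graph."""
    cfg = index.cfg
    if vertex_cache is not None and vertex_cache.cfg != cfg:
        raise ValueError("vertex cache built with a different configuration")
    t0 = time.perf_counter()
    qcode = encode_graph(Q, cfg)

    # step 1: tree traversal on counters, then spectra/size scan
    hits = index.traverse_candidates(qcode)
    primary = sorted(
        gid for gid in hits if graph_filter(qcode, index.code_store[gid], eps)
    )
    t1 = time.perf_counter()

    # step 2: candidate vertex sets
    cache = vertex_cache or VertexCodeCache(cfg)
    qv = [encode_vertex(Q, v, cfg) for v in Q.vertices]
    candidates: list[int] = []
    vertex_maps: dict[int, dict[int, list[int]]] = {}
    for gid in primary:
        if gid not in graphs:
            raise KeyError(f"indexed graph {gid} missing from database accessor")
        g = graphs[gid]
        vm = candidate_vertex_map(Q, g, qv, cache.get(g), eps)
        if vm is not None:
            candidates.append(gid)
            vertex_maps[gid] = vm
    t2 = time.perf_counter()

    # step 3: verification
    answers = [gid for gid in candidates if vf2_verify(Q, graphs[gid], vertex_maps[gid])]
    t3 = time.perf_counter()

    return QueryResult(
        query_id=Q.graph_id,
        primary_candidates=primary,
        candidates=candidates,
        candidate_vertex_maps=vertex_maps,
        answers=answers,
        stats={
            "n_database": len(index),
            "n_tree_hits": len(hits),
            "n_primary_candidates": len(primary),
            "n_candidates": len(candidates),
            "n_answers": len(answers),
            "time_filter_graph": t1 - t0,
            "time_filter_vertex": t2 - t1,
            "time_verify": t3 - t2,
        },
    )


def brute_force_query(
    graphs: Mapping[int, LabeledGraph], Q: LabeledGraph
) -> list[int]:
    """Exhaustive VF2 over every database graph (oracle / validation path)."""
    return sorted(gid for gid, g in graphs.items() if vf2_verify(Q, g))
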