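"""Synthetic labeled-graph databases, query extraction and planted pairs.

The generator emulates the classic transactional-graph benchmark shape:
N graphs with a target mean edge count, a target edge density
``2e / (n (n-1))`` and uniform vertex/edge label alphabets; query sets
are connected subgraphs with a fixed edge count grown from random
database graphs, so every query has a guaranteed (planted) answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graphs import LabeledGraph

__all__ = ["GeneratorConfig", "generate_db", "extract_query", "plant_query"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Database-generator parameters.

    n_graphs:
        Number of graphs to generate.
    avg_edges:
        Target mean edge count per graph; actual counts are Poisson
        around this value (min 1).
    density:
        Target edge density ``2e / (n (n-1))`` in (0, 1]; the vertex
        count is the smallest n whose pair count covers ``e / density``.
    n_vertex_labels, n_edge_labels:
        Label alphabet sizes; labels are drawn uniformly.
    connected:
        Patch each graph with minimal bridging edges until connected
        (default True, so query extraction always succeeds).
    seed:
        Single seed from which all sampling flows.
    """

    n_graphs: int = 10_000
    avg_edges: float = 30.0
    density: float = 0.5
    n_vertex_labels: int = 50
    n_edge_labels: int = 50
    connected: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        if self.n_vertex_labels < 1 or self.n_edge_labels < 1:
            raise ValueError("label alphabets must have >= 1 symbol")
        if self.n_graphs < 0:
            raise ValueError("n_graphs must be >= 0")
        if self.avg_edges < 1:
            raise ValueError("avg_edges must be >= 1")


def _pair_from_index(idx: int) -> tuple[int, int]:
    # inverse of the row-major upper-triangle enumeration (u < v)
    v = int((1 + math.isqrt(1 + 8 * idx)) // 2)
    u = idx - v * (v - 1) // 2
    return u, v


def _components(g: LabeledGraph) -> list[list[int]]:
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in g.vertices:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            x = stack.pop()
            for y in g.neighbors(x):
                if y not in seen:
                    seen.add(y)
                    comp.append(y)
                    stack.append(y)
        comps.append(comp)
    return comps


def _vertex_count_for(e: float, density: float) -> int:
    """Smallest n >= 2 with n(n-1)/2 >= e / density."""
    need = e / density
    n = max(2, int(math.ceil((1 + math.sqrt(1 + 8 * need)) / 2)))
    while n > 2 and (n - 1) * (n - 2) / 2 >= need:
        n -= 1
    while n * (n - 1) / 2 < need:
        n += 1
    return n


def _random_graph(
    gid: int, cfg: GeneratorConfig, rng: np.random.Generator
) -> LabeledGraph:
    e = max(1, int(rng.poisson(cfg.avg_edges)))
    # smallest n with n(n-1)/2 >= e / density
    n = _vertex_count_for(e, cfg.density)
    g = LabeledGraph(
        gid,
        [str(int(x)) for x in rng.integers(0, cfg.n_vertex_labels, size=n)],
    )
    n_pairs = n * (n - 1) // 2
    for idx in rng.choice(n_pairs, size=e, replace=False):
        u, v = _pair_from_index(int(idx))
        g.add_edge(u, v, str(int(rng.integers(0, cfg.n_edge_labels))))
    if cfg.connected:
        comps = _components(g)
        while len(comps) > 1:
            a = comps.pop(int(rng.integers(0, len(comps))))
            b = comps.pop(int(rng.integers(0, len(comps))))
            u = a[int(rng.integers(0, len(a)))]
            v = b[int(rng.integers(0, len(b)))]
            g.add_edge(u, v, str(int(rng.integers(0, cfg.n_edge_labels))))
            comps.append(a + b)
    return g


def generate_db(cfg: GeneratorConfig) -> list[LabeledGraph]:
    """Generate ``cfg.n_graphs`` labeled graphs, deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    return [_random_graph(gid, cfg, rng) for gid in range(cfg.n_graphs)]


def extract_query(
    db: list[LabeledGraph],
    n_edges: int,
    seed: int | np.random.Generator,
    query_id: int = 0,
) -> tuple[LabeledGraph, int]:
    """Extract a connected ``n_edges``-edge query from a random database
    graph by randomized edge-growth; returns (query, source graph id).

    The source graph contains the query by construction.
    """
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = [g for g in db if g.e >= n_edges]
    if not eligible:
        raise ValueError(f"no database graph has >= {n_edges} edges")
    for _ in range(1000):
        g = eligible[int(rng.integers(0, len(eligible)))]
        edges = sorted(g.edges)
        first = edges[int(rng.integers(0, len(edges)))]
        chosen = {first}
        verts = set(first)
        while len(chosen) < n_edges:
            frontier = sorted(
                e for e in g.edges if e not in chosen and (e[0] in verts or e[1] in verts)
            )
            if not frontier:
                break  # component exhausted; retry another start
            pick = frontier[int(rng.integers(0, len(frontier)))]
            chosen.add(pick)
            verts.update(pick)
        if len(chosen) == n_edges:
            kept = sorted(verts)
            remap = {old: new for new, old in enumerate(kept)}
            q = LabeledGraph(query_id, [g.vertex_labels[old] for old in kept])
            for (u, v) in sorted(chosen):
                q.add_edge(remap[u], remap[v], g.edges[(u, v)])
            return q, g.graph_id
    raise ValueError(f"could not grow a connected {n_edges}-edge query")


def plant_query(
    Q: LabeledGraph,
    host_cfg: GeneratorConfig,
    seed: int | np.random.Generator,
    host_id: int = 0,
) -> tuple[LabeledGraph, dict[int, int]]:
    """Embed ``Q`` in a random host graph with a known ground-truth map.

    The host starts as a copy of Q (vertices 0..n-1, all edges kept),
    then random decoration is added: extra vertices with uniform labels
    and extra edges drawn to approach ``host_cfg.avg_edges`` total edges
    at ``host_cfg.density``, never deleting anything.  Returns the host
    and the embedding (here the identity on Q's vertex ids).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    host = Q.copy(graph_id=host_id)
    target_e = max(Q.e, int(rng.poisson(host_cfg.avg_edges)))
    n = max(host.n, _vertex_count_for(target_e, host_cfg.density))
    for _ in range(n - host.n):
        host.vertex_labels.append(
            str(int(rng.integers(0, host_cfg.n_vertex_labels)))
        )
    host._adj = None
    n_pairs = n * (n - 1) // 2
    extra = target_e - host.e
    if extra > 0:
        free = [
            idx
            for idx in range(n_pairs)
            if _pair_from_index(idx) not in host.edges
        ]
        for idx in rng.choice(len(free), size=min(extra, len(free)), replace=False):
            u, v = _pair_from_index(free[int(idx)])
            host.add_edge(u, v, str(int(rng.integers(0, host_cfg.n_edge_labels))))
    if host_cfg.connected:
        comps = _components(host)
        while len(comps) > 1:
            a = comps.pop(int(rng.integers(0, len(comps))))
            b = comps.pop(int(rng.integers(0, len(comps))))
            u = a[int(rng.integers(0, len(a)))]
            v = b[int(rng.integers(0, len(b)))]
            host.add_edge(u, v, str(int(rng.integers(0, host_cfg.n_edge_labels))))
            comps.append(a + b)
    phi = {v: v for v in Q.vertices}
    return host, phi
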