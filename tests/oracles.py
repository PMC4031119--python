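"""Independent test oracles: brute-force enumerations and networkx-based
reference implementations that the package code never uses."""

from __future__ import annotations

import networkx as nx
import numpy as np

from lngcoding.graphs import LabeledGraph


def to_networkx(g: LabeledGraph) -> nx.Graph:
    G = nx.Graph()
    for v in g.vertices:
        G.add_node(v, label=g.vertex_labels[v])
    for (u, v), lab in g.edges.items():
        G.add_edge(u, v, label=lab)
    return G


def nx_subgraph_iso(Q: LabeledGraph, G: LabeledGraph) -> bool:
    """Reference labeled subgraph-monomorphism (non-induced) test."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        to_networkx(G),
        to_networkx(Q),
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: a["label"] == b["label"],
    )
    return gm.subgraph_is_monomorphic()


def enumerate_walks(g: LabeledGraph, start: int, length: int) -> list[int]:
    """Terminal vertices of every length-`length` walk from `start`,
    by explicit depth-first enumeration (vertices/edges may repeat)."""
    terminals: list[int] = []

    def step(v: int, remaining: int) -> None:
        if remaining == 0:
            terminals.append(v)
            return
        for u in g.neighbors(v):
            step(u, remaining - 1)

    step(start, length)
    return terminals


def bfs_ball(g: LabeledGraph, v: int, radius: int) -> set[int]:
    """Vertices within shortest-path distance `radius` of v (networkx)."""
    G = to_networkx(g)
    lengths = nx.single_source_shortest_path_length(G, v, cutoff=radius)
    return set(lengths)


def random_graph(
    rng: np.random.Generator,
    n: int,
    p: float,
    n_vlabels: int = 4,
    n_elabels: int = 3,
    gid: int = 0,
) -> LabeledGraph:
    """Labeled Erdos-Renyi-style graph (may be disconnected)."""
    g = LabeledGraph(gid, [str(int(x)) for x in rng.integers(0, n_vlabels, size=n)])
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < p:
                g.add_edge(u, v, str(int(rng.integers(0, n_elabels))))
    return g


def random_subgraph(
    rng: np.random.Generator, g: LabeledGraph, keep_v: float = 0.7, keep_e: float = 0.7
) -> LabeledGraph:
    """Random vertex- and edge-deleted subgraph (ids renumbered)."""
    kept = [v for v in g.vertices if rng.random() < keep_v]
    if not kept:
        kept = [int(rng.integers(0, g.n))]
    remap = {old: new for new, old in enumerate(kept)}
    h = LabeledGraph(g.graph_id, [g.vertex_labels[v] for v in kept])
    for (u, v), lab in g.edges.items():
        if u in remap and v in remap and rng.random() < keep_e:
            h.add_edge(remap[u], remap[v], lab)
    return h
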