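"""Raw structural features: local spanning graphs, Laplacian spectra,
walk counts and the deterministic label hash.

Three features feed the vertex/graph codes:

* the Level-N spanning graph (LNSG) of a vertex — the subgraph induced on
  all vertices within walk distance N, whose largest Laplacian eigenvalues
  form the vertex's local spectral signature;
* walk counts of length W, read off the W-th power of the adjacency
  matrix, tallied by terminal-vertex label;
* a seeded FNV-style string hash mapping label tokens (or label tuples)
  to counter-string positions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .graphs import LabeledGraph, adjacency_matrix, laplacian_matrix

__all__ = [
    "CodingConfig",
    "lnsg",
    "laplacian_spectrum",
    "walk_matrix",
    "walk_label_counts",
    "hash_label",
]

#: numerical floor for Laplacian eigenvalues (clamped to 0 above -EPS)
SPECTRAL_EPS = 1e-9


@dataclass(frozen=True)
class CodingConfig:
    """Parameters of the coding method.

    level_n:
        LNSG level N — radius of the local spanning graph (default 2).
    walk_len:
        Walk length W for the walk-count feature (default 2).
    n_eigen:
        Number t of largest Laplacian eigenvalues kept per vertex
        (default 3); spectra of smaller graphs are zero-padded.
    code_len_l / code_len_ae / code_len_walk:
        Counter-string lengths for the L, AE and nWalk codes (default 30).
    bits_per_item:
        Number k of counter positions each hashed item touches (default 1).
    hash_seed:
        Seed of the deterministic hash family; part of the index identity.
    """

    level_n: int = 2
    walk_len: int = 2
    n_eigen: int = 3
    code_len_l: int = 30
    code_len_ae: int = 30
    code_len_walk: int = 30
    bits_per_item: int = 1
    hash_seed: int = 0

    def __post_init__(self) -> None:
        if self.level_n < 0:
            raise ValueError("level_n must be >= 0")
        if self.walk_len < 1:
            raise ValueError("walk_len must be >= 1")
        if self.n_eigen < 1:
            raise ValueError("n_eigen must be >= 1")
        for name in ("code_len_l", "code_len_ae", "code_len_walk"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (1 <= self.bits_per_item <= min(
            self.code_len_l, self.code_len_ae, self.code_len_walk
        )):
            raise ValueError("bits_per_item must be in [1, min code length]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CodingConfig":
        return cls(**d)


def lnsg(g: LabeledGraph, v: int, n_level: int) -> LabeledGraph:
    """Level-N spanning graph of vertex ``v``.

    The vertex set is the breadth-first ball of radius ``n_level`` around
    ``v`` (all vertices at walk distance <= N); every edge of ``g`` between
    included vertices is retained with its label.  Kept vertices are
    renumbered 0..m-1 in ascending original-id order; labels preserved.
    """
    if not (0 <= v < g.n):
        raise ValueError(f"vertex {v} not in graph {g.graph_id}")
    if n_level < 0:
        raise ValueError("level must be >= 0")
    dist = {v: 0}
    frontier = [v]
    d = 0
    adj = g.adjacency()
    while frontier and d < n_level:
        d += 1
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
    kept = sorted(dist)
    remap = {old: new for new, old in enumerate(kept)}
    sub = LabeledGraph(g.graph_id, [g.vertex_labels[old] for old in kept])
    for (a, b), lab in g.edges.items():
        if a in remap and b in remap:
            sub.add_edge(remap[a], remap[b], lab)
    return sub


def laplacian_spectrum(g: LabeledGraph, t: int) -> np.ndarray:
    """The ``t`` largest Laplacian eigenvalues, non-ascending, zero-padded.

    Negative round-off within :data:`SPECTRAL_EPS` is clamped to 0 (the
    Laplacian is positive semidefinite).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if g.n == 0:
        return np.zeros(t)
    vals = np.linalg.eigvalsh(laplacian_matrix(g).astype(float))
    vals = vals[::-1]  # non-ascending
    vals = np.where((vals < 0) & (vals > -SPECTRAL_EPS), 0.0, vals)
    out = np.zeros(t)
    out[: min(t, g.n)] = vals[:t]
    return out


def walk_matrix(g: LabeledGraph, w: int) -> np.ndarray:
    """Integer matrix A^W; entry (i, j) counts length-W walks from i to j."""
    if w < 1:
        raise ValueError("walk length must be >= 1")
    a = adjacency_matrix(g)
    out = a.copy()
    for _ in range(w - 1):
        out = out @ a
    return out


def walk_label_counts(
    g: LabeledGraph, v: int, w: int, _walks: np.ndarray | None = None
) -> dict[str, int]:
    """Number of length-W walks from ``v``, grouped by terminal-vertex label.

    Closed walks (terminal = start) are included.  Labels with count zero
    are omitted.  ``_walks`` may carry a precomputed ``walk_matrix(g, w)``.
    """
    if not (0 <= v < g.n):
        raise ValueError(f"vertex {v} not in graph {g.graph_id}")
    walks = walk_matrix(g, w) if _walks is None else _walks
    counts: dict[str, int] = {}
    row = walks[v]
    for u in range(g.n):
        c = int(row[u])
        if c:
            lab = g.vertex_labels[u]
            counts[lab] = counts.get(lab, 0) + c
    return counts


_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


def _fnv1a(data: bytes, seed: int) -> int:
    h = (_FNV_OFFSET ^ (seed & _MASK64)) & _MASK64
    for b in data:
        h ^= b
        h = (h * _FNV_PRIME) & _MASK64
    # final avalanche (splitmix64-style) so nearby seeds decorrelate
    h = (h ^ (h >> 30)) * 0xBF58476D1CE4E5B9 & _MASK64
    h = (h ^ (h >> 27)) * 0x94D049BB133111EB & _MASK64
    return (h ^ (h >> 31)) & _MASK64


def _serialize_item(item: str | tuple) -> bytes:
    if isinstance(item, str):
        return item.encode("utf-8")
    return b"\x1f".join(str(part).encode("utf-8") for part in item)


def hash_label(item: str | tuple, s: int, k: int = 1, seed: int = 0) -> frozenset[int]:
    """Deterministically map a label token (or tuple) to ``k`` distinct
    positions in ``[0, s)``.

    The same item always hashes to the same positions for a fixed seed,
    across runs and platforms.  Distinct items may collide — collisions
    only merge counters and never break dominance.
    """
    if not (1 <= k <= s):
        raise ValueError("need 1 <= k <= s")
    data = _serialize_item(item)
    positions: set[int] = set()
    rnd = 0
    while len(positions) < k:
        positions.add(_fnv1a(data + b"\x00" + rnd.to_bytes(4, "little"), seed) % s)
        rnd += 1
    return frozenset(positions)
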