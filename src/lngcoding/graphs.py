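"""Labeled-graph data model, gSpan-dialect text I/O and matrix constructions.

The universal object is :class:`LabeledGraph`: an undirected simple graph
whose vertices and edges each carry exactly one string label.  Vertex ids
are contiguous 0-based integers and file order fixes row/column order in
the adjacency and Laplacian matrices built here; every downstream code is
order-independent (sorted or summed), so the convention is purely internal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledGraph",
    "GraphParseError",
    "parse_graph_db",
    "write_graph_db",
    "validate_graph",
    "adjacency_matrix",
    "laplacian_matrix",
]


class GraphParseError(ValueError):
    """Malformed graph-transaction text; carries the offending line number."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass
class LabeledGraph:
    """Undirected simple graph with vertex and edge labels.

    Parameters
    ----------
    graph_id:
        Non-negative identifier (database key).
    vertex_labels:
        Label of vertex ``i`` at position ``i``; the length defines ``n``.
    edges:
        Mapping from the unordered pair ``(min(u,v), max(u,v))`` to the
        edge label.  Self-loops and parallel edges are rejected by
        :func:`validate_graph`.
    """

    graph_id: int
    vertex_labels: list[str]
    edges: dict[tuple[int, int], str] = field(default_factory=dict)

    _adj: dict[int, list[int]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n(self) -> int:
        return len(self.vertex_labels)

    @property
    def e(self) -> int:
        return len(self.edges)

    @property
    def vertices(self) -> range:
        return range(self.n)

    def has_edge(self, u: int, v: int) -> bool:
        return _edge_key(u, v) in self.edges

    def edge_label(self, u: int, v: int) -> str:
        return self.edges[_edge_key(u, v)]

    def add_edge(self, u: int, v: int, label: str) -> None:
        if u == v:
            raise ValueError(f"self-loop at vertex {u}")
        key = _edge_key(u, v)
        if key in self.edges:
            raise ValueError(f"duplicate edge {key}")
        self.edges[key] = label
        self._adj = None

    def adjacency(self) -> dict[int, list[int]]:
        """Neighbor lists, sorted ascending; cached until the edge set changes."""
        if self._adj is None:
            adj: dict[int, list[int]] = {v: [] for v in self.vertices}
            for (u, v) in self.edges:
                adj[u].append(v)
                adj[v].append(u)
            for lst in adj.values():
                lst.sort()
            self._adj = adj
        return self._adj

    def neighbors(self, v: int) -> list[int]:
        return self.adjacency()[v]

    def degree(self, v: int) -> int:
        return len(self.adjacency()[v])

    def copy(self, graph_id: int | None = None) -> "LabeledGraph":
        return LabeledGraph(
            self.graph_id if graph_id is None else graph_id,
            list(self.vertex_labels),
            dict(self.edges),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledGraph):
            return NotImplemented
        return (
            self.graph_id == other.graph_id
            and self.vertex_labels == other.vertex_labels
            and self.edges == other.edges
        )


def validate_graph(g: LabeledGraph) -> list[str]:
    """Return human-readable invariant violations; empty list iff valid."""
    violations: list[str] = []
    if g.graph_id < 0:
        violations.append(f"graph id {g.graph_id} is negative")
    for i, lab in enumerate(g.vertex_labels):
        if not isinstance(lab, str) or lab == "":
            violations.append(f"vertex {i} has missing/empty label")
    for (u, v), lab in g.edges.items():
        if u == v:
            violations.append(f"self-loop at vertex {u}")
        if u > v:
            violations.append(f"edge key ({u},{v}) not in canonical (min,max) order")
        for w in (u, v):
            if not (0 <= w < g.n):
                violations.append(f"edge ({u},{v}) references undeclared vertex {w}")
        if not isinstance(lab, str) or lab == "":
            violations.append(f"edge ({u},{v}) has missing/empty label")
    return violations


def _iter_lines(source: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(source, str):
        yield from source.splitlines()
    else:
        for line in source:
            yield line.rstrip("\n")


def parse_graph_db(
    source: str | IO[str] | Iterable[str], strict: bool = True
) -> list[LabeledGraph]:
    """Parse a gSpan-dialect graph-transaction stream.

    Records look like::

        t # 0
        v 0 A
        v 1 B
        e 0 1 x

    Lines starting with ``#`` (other than the ``t # id`` header) and blank
    lines are ignored.  In strict mode any malformed line raises
    :class:`GraphParseError` naming the line number; in non-strict mode the
    offending graph is dropped with a logged warning and parsing continues
    at the next ``t`` header.
    """
    graphs: list[LabeledGraph] = []
    current: LabeledGraph | None = None
    expected_vid = 0
    bad = False  # current graph already reported invalid (non-strict)

    def fail(msg: str, ln: int) -> None:
        nonlocal bad
        if strict:
            raise GraphParseError(msg, ln)
        logger.warning("dropping graph at line %d: %s", ln, msg)
        bad = True

    def flush() -> None:
        nonlocal current, expected_vid, bad
        if current is not None and not bad:
            graphs.append(current)
        current = None
        expected_vid = 0
        bad = False

    for ln, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        tag = parts[0]
        if tag == "t":
            flush()
            if len(parts) != 3 or parts[1] != "#":
                fail(f"malformed graph header {line!r}", ln)
                current = None
                continue
            try:
                gid = int(parts[2])
            except ValueError:
                fail(f"non-integer graph id {parts[2]!r}", ln)
                current = None
                continue
            current = LabeledGraph(gid, [])
        elif tag.startswith("#"):
            continue
        elif current is None or bad:
            if current is None:
                fail(f"{tag!r} line before any graph header", ln)
        elif tag == "v":
            if len(parts) != 3:
                fail(f"malformed vertex line {line!r}", ln)
                continue
            try:
                vid = int(parts[1])
            except ValueError:
                fail(f"non-integer vertex id {parts[1]!r}", ln)
                continue
            if vid != expected_vid:
                fail(
                    f"vertex id {vid} out of order (expected {expected_vid})", ln
                )
                continue
            current.vertex_labels.append(parts[2])
            expected_vid += 1
        elif tag == "e":
            if len(parts) != 4:
                fail(f"malformed edge line {line!r}", ln)
                continue
            try:
                u, v = int(parts[1]), int(parts[2])
            except ValueError:
                fail(f"non-integer edge endpoint in {line!r}", ln)
                continue
            if u == v:
                fail(f"self-loop at vertex {u}", ln)
                continue
            if not (0 <= u < current.n and 0 <= v < current.n):
                fail(f"edge ({u},{v}) references undeclared vertex", ln)
                continue
            if current.has_edge(u, v):
                fail(f"duplicate edge ({u},{v})", ln)
                continue
            current.edges[_edge_key(u, v)] = parts[3]
        else:
            fail(f"unknown record type {tag!r}", ln)
    flush()
    return graphs


def write_graph_db(graphs: Iterable[LabeledGraph]) -> str:
    """Serialize graphs deterministically (vertices ascending, edges sorted)."""
    out: list[str] = []
    for g in graphs:
        out.append(f"t # {g.graph_id}")
        for i, lab in enumerate(g.vertex_labels):
            out.append(f"v {i} {lab}")
        for (u, v) in sorted(g.edges):
            out.append(f"e {u} {v} {g.edges[(u, v)]}")
    return "\n".join(out) + ("\n" if out else "")


def adjacency_matrix(g: LabeledGraph) -> np.ndarray:
    """0/1 adjacency matrix with zero diagonal, row i <-> vertex i."""
    a = np.zeros((g.n, g.n), dtype=np.int64)
    for (u, v) in g.edges:
        a[u, v] = 1
        a[v, u] = 1
    return a


def laplacian_matrix(g: LabeledGraph) -> np.ndarray:
    """Combinatorial Laplacian D - A (degree diagonal minus adjacency)."""
    a = adjacency_matrix(g)
    return np.diag(a.sum(axis=1)) - a
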