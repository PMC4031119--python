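"""The LnGCode-Tree: a balanced signature tree over (L, AE, nWalk) codes.

Leaves group graphs that share an identical counter-code triple; internal
nodes carry the element-wise maximum of their children's codes, so a whole
subtree can be pruned when some counter position falls strictly below the
query's.  The per-graph spectra (Lapsseqs) are deliberately *not* stored
in tree nodes — they live in the flat per-graph code store and are applied
as a post-traversal scan.

Structure is S-tree/R-tree-like: all leaves at equal depth, fan-out
between ``m`` and ``M`` except at the root, overflow handled by a
deterministic quadratic-style split, deletion by lazy underflow.
"""

from __future__ import annotations

import io
import json
import struct
from typing import Iterable, Iterator

import numpy as np

from .codes import GraphCode
from .features import CodingConfig

__all__ = ["LnGCodeTree", "TreeNode", "build_index"]

_MAGIC = b"LNGC"
_FORMAT_VERSION = 1

_Triple = tuple[np.ndarray, np.ndarray, np.ndarray]


class TreeNode:
    """Leaf or internal node; leaves hold graph ids, internal nodes children."""

    __slots__ = ("is_leaf", "code", "children", "graph_ids", "parent")

    def __init__(self, is_leaf: bool, code: _Triple):
        self.is_leaf = is_leaf
        self.code = code
        self.children: list[TreeNode] = []
        self.graph_ids: list[int] = []
        self.parent: TreeNode | None = None


def _code_key(triple: _Triple) -> bytes:
    return b"".join(arr.tobytes() for arr in triple)


def _triple_max(a: _Triple, b: _Triple) -> _Triple:
    return tuple(np.maximum(x, y) for x, y in zip(a, b))  # type: ignore[return-value]


def _triple_copy(a: _Triple) -> _Triple:
    return tuple(x.copy() for x in a)  # type: ignore[return-value]


def _enlargement(node_code: _Triple, new_code: _Triple) -> int:
    """Total counter increase needed for node_code to cover new_code."""
    return int(
        sum(np.maximum(0, n - c).sum() for c, n in zip(node_code, new_code))
    )


def _l1_distance(a: _Triple, b: _Triple) -> int:
    return int(sum(np.abs(x - y).sum() for x, y in zip(a, b)))


def recompute_node_code(node: TreeNode) -> _Triple:
    """Leaf: the shared graph triple; internal: element-wise max of children."""
    if node.is_leaf:
        if not node.graph_ids:
            raise ValueError("cannot recompute code of an empty leaf")
        return node.code
    if not node.children:
        raise ValueError("cannot recompute code of an empty internal node")
    code = _triple_copy(node.children[0].code)
    for child in node.children[1:]:
        code = _triple_max(code, child.code)
    return code


class LnGCodeTree:
    """Balanced signature tree plus the flat graph-code store.

    Parameters
    ----------
    cfg:
        The coding configuration the stored codes were built with; queries
        must be encoded with an equal configuration.
    m, M:
        Minimum and maximum fan-out of internal nodes (root excepted).
    """

    def __init__(self, cfg: CodingConfig, m: int = 2, M: int = 8):
        if not (2 <= m <= (M + 1) // 2):
            raise ValueError("fan-out bounds must satisfy 2 <= m <= ceil(M/2)")
        self.cfg = cfg
        self.m = m
        self.M = M
        self.root: TreeNode | None = None
        self.code_store: dict[int, GraphCode] = {}
        self._leaf_by_key: dict[bytes, TreeNode] = {}

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.code_store)

    def __contains__(self, graph_id: int) -> bool:
        return graph_id in self.code_store

    def _check_query_code(self, code: GraphCode) -> None:
        expect = (self.cfg.code_len_l, self.cfg.code_len_ae, self.cfg.code_len_walk)
        got = (code.l.size, code.ae.size, code.nwalk.size)
        if expect != got:
            raise ValueError(
                f"query code lengths {got} do not match index config {expect}"
            )

    def traverse_candidates(self, query_code: GraphCode) -> set[int]:
        """All graph ids in leaves whose path codes dominate the query's.

        Because leaves group identical codes and internal codes are tight
        element-wise maxima, the result equals the linear-scan set
        ``{id : stored (L, AE, nWalk) dominates the query's}``.
        """
        self._check_query_code(query_code)
        q = query_code.counter_triple()
        out: set[int] = set()
        if self.root is None:
            return out
        stack = [self.root]
        while stack:
            node = stack.pop()
            if any(np.any(c < qc) for c, qc in zip(node.code, q)):
                continue
            if node.is_leaf:
                out.update(node.graph_ids)
            else:
                stack.extend(node.children)
        return out

    # -- mutation --------------------------------------------------------

    def insert_graph(self, graph_id: int, code: GraphCode) -> None:
        if graph_id in self.code_store:
            raise ValueError(f"duplicate graph id {graph_id}")
        self._check_query_code(code)
        self.code_store[graph_id] = code
        triple = _triple_copy(code.counter_triple())
        key = _code_key(triple)
        leaf = self._leaf_by_key.get(key)
        if leaf is not None:
            leaf.graph_ids.append(graph_id)
            return
        leaf = TreeNode(True, triple)
        leaf.graph_ids.append(graph_id)
        self._leaf_by_key[key] = leaf
        self._insert_leaf(leaf)

    def _insert_leaf(self, leaf: TreeNode) -> None:
        if self.root is None:
            self.root = leaf
            return
        if self.root.is_leaf:
            new_root = TreeNode(False, _triple_max(self.root.code, leaf.code))
            for child in (self.root, leaf):
                child.parent = new_root
                new_root.children.append(child)
            self.root = new_root
            return
        # descend to the bottom internal level (children are leaves)
        node = self.root
        while not node.children[0].is_leaf:
            node = self._choose_subtree(node, leaf.code)
        node.children.append(leaf)
        leaf.parent = node
        self._adjust_upward(node, leaf.code)

    def _choose_subtree(self, node: TreeNode, code: _Triple) -> TreeNode:
        best = None
        best_rank = None
        for i, child in enumerate(node.children):
            rank = (
                _enlargement(child.code, code),
                int(sum(c.sum() for c in child.code)),
                i,
            )
            if best_rank is None or rank < best_rank:
                best, best_rank = child, rank
        assert best is not None
        return best

    def _adjust_upward(self, node: TreeNode, new_code: _Triple) -> None:
        # enlarge ancestor codes, splitting any overflowing node
        cur: TreeNode | None = node
        while cur is not None:
            cur.code = _triple_max(cur.code, new_code)
            if not cur.is_leaf and len(cur.children) > self.M:
                self._split(cur)
            cur = cur.parent

    def _split(self, node: TreeNode) -> None:
        entries = node.children
        # seeds: the pair with maximal L1 distance between code triples
        best_pair = (0, 1)
        best_d = -1
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                d = _l1_distance(entries[i].code, entries[j].code)
                if d > best_d:
                    best_d = d
                    best_pair = (i, j)
        si, sj = best_pair
        groups: list[list[TreeNode]] = [[entries[si]], [entries[sj]]]
        codes = [_triple_copy(entries[si].code), _triple_copy(entries[sj].code)]
        rest = [e for idx, e in enumerate(entries) if idx not in (si, sj)]
        for pos, e in enumerate(rest):
            remaining = len(rest) - pos
            forced = None
            for gi in (0, 1):
                if len(groups[gi]) + remaining == self.m:
                    forced = gi
            if forced is not None:
                gi = forced
            else:
                enl = [_enlargement(codes[gi], e.code) for gi in (0, 1)]
                if enl[0] != enl[1]:
                    gi = 0 if enl[0] < enl[1] else 1
                else:
                    gi = 0 if len(groups[0]) <= len(groups[1]) else 1
            groups[gi].append(e)
            codes[gi] = _triple_max(codes[gi], e.code)

        sibling = TreeNode(False, codes[1])
        node.children = groups[0]
        node.code = codes[0]
        for child in groups[0]:
            child.parent = node
        sibling.children = groups[1]
        for child in groups[1]:
            child.parent = sibling

        parent = node.parent
        if parent is None:
            new_root = TreeNode(False, _triple_max(node.code, sibling.code))
            for child in (node, sibling):
                child.parent = new_root
                new_root.children.append(child)
            self.root = new_root
        else:
            sibling.parent = parent
            parent.children.append(sibling)
            # parent may now overflow; handled by the caller's upward loop

    def remove_graph(self, graph_id: int) -> None:
        code = self.code_store.pop(graph_id, None)
        if code is None:
            raise KeyError(f"unknown graph id {graph_id}")
        key = _code_key(code.counter_triple())
        leaf = self._leaf_by_key[key]
        leaf.graph_ids.remove(graph_id)
        if leaf.graph_ids:
            return
        del self._leaf_by_key[key]
        self._remove_node(leaf)

    def _remove_node(self, node: TreeNode) -> None:
        parent = node.parent
        if parent is None:
            self.root = None
            return
        parent.children.remove(node)
        node.parent = None
        if not parent.children:
            self._remove_node(parent)
            return
        # exact recomputation up the path (codes may shrink)
        cur: TreeNode | None = parent
        while cur is not None:
            cur.code = recompute_node_code(cur)
            cur = cur.parent
        # collapse a single-child root to keep leaves equidistant
        while self.root is not None and not self.root.is_leaf and len(self.root.children) == 1:
            self.root = self.root.children[0]
            self.root.parent = None

    # -- integrity -------------------------------------------------------

    def iter_leaves(self) -> Iterator[TreeNode]:
        if self.root is None:
            return
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(node.children)

    def check_invariants(self) -> None:
        """Raise AssertionError on any structural-invariant violation."""
        seen: set[int] = set()
        depths: set[int] = set()

        def visit(node: TreeNode, depth: int) -> None:
            if node.is_leaf:
                assert node.graph_ids, "empty leaf in tree"
                depths.add(depth)
                key = _code_key(node.code)
                for gid in node.graph_ids:
                    assert gid not in seen, f"graph {gid} in two leaves"
                    seen.add(gid)
                    stored = self.code_store[gid].counter_triple()
                    assert _code_key(stored) == key, "leaf groups differing codes"
            else:
                assert node.children, "empty internal node"
                expect = recompute_node_code(node)
                assert _code_key(node.code) == _code_key(expect), "stale internal code"
                for child in node.children:
                    assert child.parent is node, "broken parent link"
                    for c, ch in zip(node.code, child.code):
                        assert np.all(c >= ch), "parent does not dominate child"
                    visit(child, depth + 1)

        if self.root is not None:
            assert self.root.parent is None
            visit(self.root, 0)
        assert seen == set(self.code_store), "tree/code-store id mismatch"
        assert len(depths) <= 1, f"leaves at unequal depths {depths}"

    # -- persistence -----------------------------------------------------

    def save(self, path: str) -> None:
        """Persist to a single file; bit-exact round-trip.

        Layout: magic, format version, length-prefixed JSON header
        (config, fan-out bounds, graph count), then per graph the id,
        sizes, fixed-width little-endian int64 counters and float64
        spectra, then the tree topology in preorder (leaves as id lists).
        """
        buf = io.BytesIO()
        buf.write(_MAGIC)
        buf.write(struct.pack("<I", _FORMAT_VERSION))
        header = json.dumps(
            {"cfg": self.cfg.to_dict(), "m": self.m, "M": self.M,
             "n_graphs": len(self.code_store)},
            sort_keys=True,
        ).encode("utf-8")
        buf.write(struct.pack("<I", len(header)))
        buf.write(header)
        for gid in sorted(self.code_store):
            c = self.code_store[gid]
            buf.write(struct.pack("<qii", gid, c.n_vertices, c.n_edges))
            for arr in (c.l, c.ae, c.nwalk):
                buf.write(arr.astype("<i8").tobytes())
            buf.write(c.lapsseqs.astype("<f8").tobytes())
        self._write_topology(buf)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    def _write_topology(self, buf: io.BytesIO) -> None:
        def visit(node: TreeNode) -> None:
            if node.is_leaf:
                buf.write(struct.pack("<BI", 1, len(node.graph_ids)))
                for gid in node.graph_ids:
                    buf.write(struct.pack("<q", gid))
            else:
                buf.write(struct.pack("<BI", 0, len(node.children)))
                for child in node.children:
                    visit(child)

        if self.root is None:
            buf.write(struct.pack("<B", 2))
        else:
            buf.write(struct.pack("<B", 3))
            visit(self.root)

    @classmethod
    def load(cls, path: str) -> "LnGCodeTree":
        with open(path, "rb") as fh:
            data = fh.read()
        buf = io.BytesIO(data)
        if buf.read(4) != _MAGIC:
            raise ValueError(f"{path}: not an LnGCode-Tree index file")
        (version,) = struct.unpack("<I", buf.read(4))
        if version != _FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported index format version {version}")
        (hlen,) = struct.unpack("<I", buf.read(4))
        header = json.loads(buf.read(hlen).decode("utf-8"))
        cfg = CodingConfig.from_dict(header["cfg"])
        tree = cls(cfg, header["m"], header["M"])
        t = cfg.n_eigen
        for _ in range(header["n_graphs"]):
            gid, nv, ne = struct.unpack("<qii", buf.read(16))
            arrs = []
            for size in (cfg.code_len_l, cfg.code_len_ae, cfg.code_len_walk):
                arrs.append(
                    np.frombuffer(buf.read(8 * size), dtype="<i8").astype(np.int64)
                )
            laps = np.frombuffer(buf.read(8 * t * nv), dtype="<f8").reshape(t, nv).copy()
            tree.code_store[gid] = GraphCode(arrs[0], arrs[1], arrs[2], laps, nv, ne)

        (marker,) = struct.unpack("<B", buf.read(1))
        if marker == 2:
            tree.root = None
            return tree

        def read_node() -> TreeNode:
            kind, count = struct.unpack("<BI", buf.read(5))
            if kind == 1:
                ids = [struct.unpack("<q", buf.read(8))[0] for _ in range(count)]
                code = _triple_copy(tree.code_store[ids[0]].counter_triple())
                leaf = TreeNode(True, code)
                leaf.graph_ids = ids
                tree._leaf_by_key[_code_key(code)] = leaf
                return leaf
            node = TreeNode(False, None)  # type: ignore[arg-type]
            for _ in range(count):
                child = read_node()
                child.parent = node
                node.children.append(child)
            node.code = recompute_node_code(node)
            return node

        tree.root = read_node()
        return tree


def build_index(
    codes: dict[int, GraphCode] | Iterable[tuple[int, GraphCode]],
    cfg: CodingConfig,
    m: int = 2,
    M: int = 8,
) -> LnGCodeTree:
    """Build a tree by sequential insertion (build == fold of insert)."""
    tree = LnGCodeTree(cfg, m, M)
    items = codes.items() if isinstance(codes, dict) else codes
    for gid, code in items:
        tree.insert_graph(gid, code)
    return tree
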