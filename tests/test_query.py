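"""Filtering conditions, VF2 verification and the full pipeline."""

import numpy as np
import pytest

from lngcoding.codes import encode_graph, encode_vertex
from lngcoding.features import CodingConfig
from lngcoding.graphs import LabeledGraph
from lngcoding.index import build_index
from lngcoding.query import (
    VertexCodeCache,
    brute_force_query,
    candidate_vertex_map,
    graph_filter,
    run_query,
    vertex_filter,
    vf2_verify,
)
from lngcoding.synth import GeneratorConfig, extract_query, generate_db, plant_query

from oracles import nx_subgraph_iso, random_graph


class TestGraphFilter:
    def test_reflexive(self, triangle, cfg):
        c = encode_graph(triangle, cfg)
        assert graph_filter(c, c)

    def test_query_larger_fails(self, k2, triangle, cfg):
        assert not graph_filter(encode_graph(triangle, cfg), encode_graph(k2, cfg))

    def test_config_mismatch_raises(self, k2, cfg):
        other = CodingConfig(code_len_l=5, code_len_ae=5, code_len_walk=5)
        with pytest.raises(ValueError):
            graph_filter(encode_graph(k2, cfg), encode_graph(k2, other))

    def test_planted_pairs_always_pass_and_rejections_sound(self, rng, cfg):
        """Containment implies the filter passes; every rejected random
        pair is confirmed non-containing by the reference matcher."""
        host_cfg = GeneratorConfig(
            n_graphs=1, avg_edges=10, density=0.4,
            n_vertex_labels=3, n_edge_labels=2, seed=0,
        )
        for _ in range(40):
            q = random_graph(rng, int(rng.integers(2, 6)), 0.5, 3, 2)
            host, _phi = plant_query(q, host_cfg, rng)
            assert graph_filter(encode_graph(q, cfg), encode_graph(host, cfg))
        for _ in range(40):
            q = random_graph(rng, int(rng.integers(2, 6)), 0.5, 3, 2)
            g = random_graph(rng, int(rng.integers(2, 8)), 0.4, 3, 2)
            if not graph_filter(encode_graph(q, cfg), encode_graph(g, cfg)):
                assert not nx_subgraph_iso(q, g)


class TestVertexFilter:
    def test_self(self, triangle, cfg):
        vc = encode_vertex(triangle, 0, cfg)
        assert vertex_filter(vc, vc)

    def test_label_mismatch_fails(self, triangle, cfg):
        assert not vertex_filter(
            encode_vertex(triangle, 0, cfg), encode_vertex(triangle, 1, cfg)
        )

    def test_planted_pairs_pass_along_embedding(self, rng, cfg):
        host_cfg = GeneratorConfig(
            n_graphs=1, avg_edges=10, density=0.4,
            n_vertex_labels=3, n_edge_labels=2, seed=0,
        )
        for _ in range(30):
            q = random_graph(rng, int(rng.integers(2, 6)), 0.5, 3, 2)
            host, phi = plant_query(q, host_cfg, rng)
            for v in q.vertices:
                assert vertex_filter(
                    encode_vertex(q, v, cfg), encode_vertex(host, phi[v], cfg)
                )


class TestCandidateVertexMap:
    def test_self_maps_include_identity(self, triangle, cfg):
        codes = [encode_vertex(triangle, v, cfg) for v in triangle.vertices]
        vm = candidate_vertex_map(triangle, triangle, codes, codes)
        assert vm is not None
        for v in triangle.vertices:
            assert v in vm[v]

    def test_absent_label_prunes(self, k2, triangle, cfg):
        q = LabeledGraph(1, ["Z"])
        qc = [encode_vertex(q, 0, cfg)]
        gc = [encode_vertex(triangle, v, cfg) for v in triangle.vertices]
        assert candidate_vertex_map(q, triangle, qc, gc) is None


class TestVF2:
    def test_edge_in_path(self):
        q = LabeledGraph(0, ["A", "B"])
        q.add_edge(0, 1, "x")
        g = LabeledGraph(1, ["A", "B", "C"])
        g.add_edge(0, 1, "x")
        g.add_edge(1, 2, "y")
        assert vf2_verify(q, g)

    def test_triangle_not_in_tree(self, triangle, star4):
        assert not vf2_verify(triangle, star4)

    def test_edge_label_respected(self, k2):
        g = LabeledGraph(1, ["A", "B"])
        g.add_edge(0, 1, "DIFFERENT")
        assert not vf2_verify(k2, g)

    def test_returns_valid_embedding(self, rng):
        q = random_graph(rng, 4, 0.6, 3, 2)
        host, _phi = plant_query(
            q,
            GeneratorConfig(n_graphs=1, avg_edges=12, density=0.4,
                            n_vertex_labels=3, n_edge_labels=2, seed=0),
            rng,
        )
        found, emb = vf2_verify(q, host, return_embedding=True)
        assert found
        assert len(set(emb.values())) == q.n
        for (u, v), lab in q.edges.items():
            assert host.has_edge(emb[u], emb[v])
            assert host.edge_label(emb[u], emb[v]) == lab

    def test_agrees_with_reference_matcher(self, rng):
        """200 random (Q, G) pairs against the networkx monomorphism
        oracle; sampling is tilted so both outcomes occur."""
        hits = misses = 0
        for _ in range(200):
            q = random_graph(rng, int(rng.integers(1, 6)), 0.5, 2, 2)
            g = random_graph(rng, int(rng.integers(1, 9)), 0.5, 2, 2)
            expect = nx_subgraph_iso(q, g)
            assert vf2_verify(q, g) == expect
            hits += expect
            misses += not expect
        assert hits > 10 and misses > 10

    def test_seed_map_restricts_but_preserves_truth(self, rng, cfg):
        host_cfg = GeneratorConfig(
            n_graphs=1, avg_edges=10, density=0.4,
            n_vertex_labels=3, n_edge_labels=2, seed=0,
        )
        for _ in range(20):
            q = random_graph(rng, int(rng.integers(2, 5)), 0.5, 3, 2)
            host, _phi = plant_query(q, host_cfg, rng)
            qv = [encode_vertex(q, v, cfg) for v in q.vertices]
            gv = [encode_vertex(host, u, cfg) for u in host.vertices]
            vm = candidate_vertex_map(q, host, qv, gv)
            assert vm is not None
            assert vf2_verify(q, host, seed_map=vm)


@pytest.fixture(scope="module")
def small_db():
    cfg = CodingConfig()
    db = generate_db(
        GeneratorConfig(n_graphs=80, avg_edges=12, density=0.35,
                        n_vertex_labels=4, n_edge_labels=2, seed=17)
    )
    dbm = {g.graph_id: g for g in db}
    tree = build_index({gid: encode_graph(g, cfg) for gid, g in dbm.items()}, cfg)
    return db, dbm, tree


class TestRunQuery:
    def test_planted_query_answered(self, small_db, rng):
        db, dbm, tree = small_db
        q, src = extract_query(db, 5, rng, query_id=0)
        res = run_query(tree, dbm, q)
        assert src in res.answers

    def test_absent_label_empty_sets(self, small_db):
        _db, dbm, tree = small_db
        q = LabeledGraph(0, ["ABSENT", "ABSENT"])
        q.add_edge(0, 1, "z")
        res = run_query(tree, dbm, q)
        assert res.primary_candidates == res.candidates == res.answers == []

    def test_nested_sets_and_brute_force_agreement(self, small_db, rng):
        db, dbm, tree = small_db
        cache = VertexCodeCache(tree.cfg)
        for qid in range(20):
            q, _src = extract_query(db, int(rng.integers(3, 9)), rng, query_id=qid)
            res = run_query(tree, dbm, q, vertex_cache=cache)
            assert set(res.answers) <= set(res.candidates) <= set(res.primary_candidates)
            assert res.answers == brute_force_query(dbm, q)
            for gid in res.candidates:
                assert all(res.candidate_vertex_maps[gid][v] for v in q.vertices)

    def test_answers_match_reference_matcher(self, small_db, rng):
        """End-to-end soundness+completeness against the independent
        networkx oracle (not the in-repo VF2)."""
        db, dbm, tree = small_db
        for qid in range(8):
            q, _src = extract_query(db, int(rng.integers(4, 8)), rng, query_id=qid)
            res = run_query(tree, dbm, q)
            expect = sorted(gid for gid, g in dbm.items() if nx_subgraph_iso(q, g))
            assert res.answers == expect

    def test_determinism(self, small_db, rng):
        db, dbm, tree = small_db
        q, _src = extract_query(db, 6, np.random.default_rng(4), query_id=0)
        r1 = run_query(tree, dbm, q)
        r2 = run_query(tree, dbm, q)
        assert r1.primary_candidates == r2.primary_candidates
        assert r1.candidates == r2.candidates
        assert r1.answers == r2.answers
        assert r1.candidate_vertex_maps == r2.candidate_vertex_maps
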