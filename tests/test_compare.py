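import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

import coopnet as cn
from coopnet.io import InsufficientDataError, LimitError, UsageError


def _digraph(edges, nodes=None):
    g = nx.DiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestMoralize:
    def test_collider_parents_married(self):
        m = cn.moralize(_digraph([("a", "c"), ("b", "c")]))
        assert m.edges == {frozenset(e) for e in [("a", "c"), ("b", "c"), ("a", "b")]}

    def test_chain_adds_no_marriage(self):
        m = cn.moralize(_digraph([("a", "b"), ("b", "c")]))
        assert m.edges == {frozenset(("a", "b")), frozenset(("b", "c"))}

    def test_already_married_parents_not_duplicated(self):
        g = _digraph([("a", "b"), ("a", "c"), ("c", "b")])
        m = cn.moralize(g)
        # b's parents {a, c} are already connected by a->c
        assert m.edges == {frozenset(("a", "b")), frozenset(("a", "c")),
                           frozenset(("c", "b"))}

    def test_matches_networkx_oracle_on_all_small_dags(self):
        """Independent reference: networkx's textbook moral-graph construction,
        over every DAG on up to 4 labeled nodes."""
        for n in (2, 3, 4):
            names = [chr(ord("a") + i) for i in range(n)]
            for edge_idx in cn.enumerate_dags(n):
                g = _digraph([(names[u], names[v]) for u, v in edge_idx],
                             nodes=names)
                mine = {tuple(sorted(e)) for e in cn.moralize(g).edges}
                oracle = {tuple(sorted(e)) for e in nx.moral_graph(g).edges()}
                assert mine == oracle


class TestCommonSubgraph:
    def _mg(self, edges, name=""):
        nodes = sorted({x for e in edges for x in e})
        return cn.MoralGraph(nodes=nodes,
                             edges={frozenset(e) for e in edges}, source=name)

    def test_identical_graphs_return_largest_component(self):
        g = self._mg([("a", "b"), ("b", "c"), ("x", "y")])
        sub = cn.common_subgraph([g, g], 2)
        assert sub.edges == {frozenset(("a", "b")), frozenset(("b", "c"))}
        assert sub.nodes == ["a", "b", "c"]

    def test_edge_disjoint_graphs_empty(self):
        sub = cn.common_subgraph(
            [self._mg([("a", "b")]), self._mg([("c", "d")])], 2)
        assert sub.edges == set() and sub.nodes == []

    def test_support_threshold_exact(self):
        g1 = self._mg([("a", "b"), ("c", "d")])
        g2 = self._mg([("a", "b")])
        g3 = self._mg([("e", "f")])
        sub = cn.common_subgraph([g1, g2, g3], 2)
        assert sub.edges == {frozenset(("a", "b"))}
        assert sub.support[frozenset(("a", "b"))] == 2

    def test_monotone_in_min_support(self):
        rng = np.random.default_rng(4)
        graphs = []
        labels = [chr(ord("a") + i) for i in range(8)]
        for _ in range(5):
            edges = [tuple(rng.choice(labels, 2, replace=False)) for _ in range(8)]
            graphs.append(self._mg([e for e in edges if e[0] != e[1]]))
        prev = None
        for ms in (1, 2, 3, 4, 5):
            sub = cn.common_subgraph(graphs, ms)
            kept = set(sub.support)
            if prev is not None:
                assert len(sub.edges) <= prev
            prev = len(sub.edges)
            assert all(c >= ms for c in sub.support.values())

    def test_min_support_bounds(self):
        g = self._mg([("a", "b")])
        with pytest.raises(UsageError):
            cn.common_subgraph([g, g], 3)
        with pytest.raises(UsageError):
            cn.common_subgraph([g], 1)


class TestMarkovNeighborhood:
    def _net(self, edges):
        texts = sorted({t for e in edges for t in e})
        nodes = {t: cn.ContactNodeId.parse(t) for t in texts}
        return cn.BayesianNetwork(
            nodes=list(nodes.values()),
            edges=[(nodes[u], nodes[v]) for u, v in edges],
        )

    def test_chain_midpoint(self):
        net = self._net([("1×50_G.H5.01", "2×51_G.H5.02"),
                         ("2×51_G.H5.02", "3×52_G.H5.03")])
        assert cn.markov_neighborhood(net, "2×51_G.H5.02") == {
            "1×50_G.H5.01", "3×52_G.H5.03"}

    def test_isolated_node_empty(self):
        iso = cn.ContactNodeId.parse("6×30_G.H5.09")
        net = cn.BayesianNetwork(nodes=[iso], edges=[])
        assert cn.markov_neighborhood(net, iso) == set()

    def test_collider_excludes_coparent(self):
        """Adjacency, not the Markov blanket: the other parent of a shared
        child is NOT in the neighborhood."""
        net = self._net([("1×50_G.H5.01", "3×52_G.H5.03"),
                         ("2×51_G.H5.02", "3×52_G.H5.03")])
        assert cn.markov_neighborhood(net, "1×50_G.H5.01") == {"3×52_G.H5.03"}

    def test_unknown_node_rejected(self):
        net = self._net([("1×50_G.H5.01", "2×51_G.H5.02")])
        with pytest.raises(LookupError):
            cn.markov_neighborhood(net, "9×99_G.H5.99")


class TestEmpiricalJoint:
    def _m(self, arr):
        arr = np.asarray(arr, dtype=np.uint8)
        labels = [cn.ContactNodeId.parse(f"{j+1}×50_G.H5.{j:02d}")
                  for j in range(arr.shape[1])]
        return cn.FingerprintMatrix(labels, arr)

    def test_identical_frames_point_mass(self):
        m = self._m([[1, 0]] * 6)
        j = cn.empirical_joint(m, m.node_texts, pseudocount=0.0)
        assert j.probabilities[1] == pytest.approx(1.0)  # state (1,0) -> index 1
        assert j.probabilities.sum() == pytest.approx(1.0)

    def test_zero_frames_zero_pseudocount_guarded(self):
        m = self._m(np.zeros((0, 2)))
        with pytest.raises(UsageError):
            cn.empirical_joint(m, m.node_texts, pseudocount=0.0)

    def test_uniform_data_converges_to_quarter(self):
        rng = np.random.default_rng(8)
        m = self._m(rng.integers(0, 2, size=(10000, 2)))
        j = cn.empirical_joint(m, m.node_texts)
        assert np.allclose(j.probabilities, 0.25, atol=0.02)

    def test_pseudocount_smoothing(self):
        m = self._m([[0, 0]] * 4)
        j = cn.empirical_joint(m, m.node_texts, pseudocount=0.5)
        assert j.probabilities[0] == pytest.approx(4.5 / 6.0)
        assert j.probabilities[1:].sum() == pytest.approx(1.5 / 6.0)

    def test_state_cap(self):
        m = self._m(np.zeros((2, 3)))
        with pytest.raises(LimitError):
            cn.empirical_joint(m, m.node_texts, state_cap=4)


class TestJSD:
    def _dist(self, probs):
        m = int(math.log2(len(probs)))
        nodes = [f"{j+1}×50_G.H5.{j:02d}" for j in range(m)]
        return cn.JointDistribution(nodes, np.asarray(probs, dtype=float))

    def test_identity_is_zero(self):
        p = self._dist([0.1, 0.2, 0.3, 0.4])
        assert cn.jsd(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_supports_reach_ln2(self):
        p = self._dist([0.5, 0.5, 0.0, 0.0])
        q = self._dist([0.0, 0.0, 0.5, 0.5])
        assert cn.jsd(p, q) == pytest.approx(math.log(2.0), abs=1e-12)

    def test_mismatched_subsets_rejected(self):
        p = self._dist([0.5, 0.5])
        q = cn.JointDistribution(["9×99_G.H5.99"], np.array([0.5, 0.5]))
        with pytest.raises(UsageError):
            cn.jsd(p, q)

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
           st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_bounds_and_scipy_oracle(self, raw_p, raw_q):
        p = self._dist(np.array(raw_p) / np.sum(raw_p))
        q = self._dist(np.array(raw_q) / np.sum(raw_q))
        d = cn.jsd(p, q)
        assert d == pytest.approx(cn.jsd(q, p), abs=1e-12)
        assert -1e-12 <= d <= math.log(2.0) + 1e-12
        oracle = jensenshannon(p.probabilities, q.probabilities, base=math.e) ** 2
        assert d == pytest.approx(float(oracle), abs=1e-9)


class TestJSDMatrix:
    def test_identical_datasets_zero_matrix(self, bundle):
        m = bundle.fingerprints
        nodes = m.node_texts[:3]
        mat, names, omitted = cn.jsd_matrix({"a": m, "b": m}, nodes)
        assert np.allclose(mat, 0.0)
        assert names == ["a", "b"] and omitted == []

    def test_symmetric_zero_diagonal(self, bundle):
        m1 = bundle.fingerprints
        m2 = cn.sample_fingerprints(
            cn.planted_model(n_nodes=20, n_frames=500, seed=99),
            node_labels=m1.node_labels)
        mat, _, _ = cn.jsd_matrix([m1, m2], m1.node_texts[:4])
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)

    def test_datasets_missing_nodes_omitted(self, bundle):
        m = bundle.fingerprints
        small = cn.FingerprintMatrix(m.node_labels[:2], m.values[:, :2])
        mat, names, omitted = cn.jsd_matrix(
            {"full": m, "full2": m, "partial": small}, m.node_texts[:3])
        assert omitted == ["partial"]
        assert names == ["full", "full2"]

    def test_too_few_eligible_rejected(self, bundle):
        m = bundle.fingerprints
        with pytest.raises(InsufficientDataError):
            cn.jsd_matrix({"only": m}, m.node_texts[:2])

    def test_two_population_separation(self):
        """Datasets from one planted joint sit closer to each other than to
        datasets from a different planted joint."""
        base_a = cn.planted_model(n_nodes=6, edge_prob=0.5, n_frames=5000, seed=1)
        base_b = cn.planted_model(n_nodes=6, edge_prob=0.5, n_frames=5000, seed=2)
        labels = [cn.ContactNodeId.parse(f"{j+1}×50_G.H5.{j:02d}") for j in range(6)]

        def draw(model, seed):
            m = cn.PlantedModel(model.nodes, model.parents, model.cpts,
                                n_frames=5000, seed=seed)
            return cn.sample_fingerprints(m, node_labels=labels)

        sets = {"a1": draw(base_a, 11), "a2": draw(base_a, 12),
                "b1": draw(base_b, 21), "b2": draw(base_b, 22)}
        mat, names, _ = cn.jsd_matrix(sets, [l.canonical_text for l in labels])
        idx = {n: i for i, n in enumerate(names)}
        within = [mat[idx["a1"], idx["a2"]], mat[idx["b1"], idx["b2"]]]
        across = [mat[idx[a], idx[b]] for a in ("a1", "a2") for b in ("b1", "b2")]
        assert max(within) < min(across)
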