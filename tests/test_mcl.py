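"""MCL flow matrices, operators, and cluster extraction."""

import numpy as np
import pytest

from conftest import random_network
from dyncomplex.io import PPINetwork
from dyncomplex.mcl import (
    AttractorRecord,
    MCLParams,
    apply_penalty,
    build_adjacency,
    expand,
    filter_min_size,
    inflate,
    normalize,
    prune,
    run_mcl,
)


def triangle(prefix=""):
    return [(f"{prefix}A", f"{prefix}B"), (f"{prefix}B", f"{prefix}C"), (f"{prefix}A", f"{prefix}C")]


class TestBuildAdjacency:
    def test_unweighted_triangle_all_ones(self):
        fm = build_adjacency(PPINetwork.from_edges(triangle()))
        assert np.array_equal(fm.adj, np.ones((3, 3)))

    def test_diagonal_is_max_incident_weight(self):
        net = PPINetwork.from_edges([("A", "B", 0.2), ("A", "C", 0.8)])
        fm = build_adjacency(net)
        i = {n: k for k, n in enumerate(fm.order)}
        assert fm.adj[i["A"], i["A"]] == 0.8
        assert fm.adj[i["B"], i["B"]] == 0.2
        assert fm.adj[i["C"], i["C"]] == 0.8

    def test_isolated_node_unit_diagonal(self):
        net = PPINetwork.from_edges(triangle(), nodes=["A", "B", "C", "D"])
        fm = build_adjacency(net)
        i = fm.order.index("D")
        assert fm.adj[i, i] == 1.0
        assert fm.adj[i, :].sum() == 1.0

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            build_adjacency(PPINetwork())


class TestOperators:
    def test_normalize_triangle_columns_equal_thirds(self):
        fm = normalize(build_adjacency(PPINetwork.from_edges(triangle())))
        assert np.allclose(fm.mat, 1 / 3)

    def test_normalize_column_sums_one(self, rng):
        for _ in range(20):
            fm = normalize(build_adjacency(random_network(rng)))
            assert np.allclose(fm.mat.sum(axis=0), 1.0, atol=1e-12)

    def test_expand_identity(self):
        assert np.array_equal(expand(np.eye(4)), np.eye(4))

    def test_expand_matches_repeated_multiplication(self, rng):
        m = rng.random((5, 5))
        m /= m.sum(axis=0)
        assert np.allclose(expand(m, 3), m @ m @ m)

    def test_inflate_ic1_identity(self, rng):
        m = rng.random((4, 4))
        m /= m.sum(axis=0)
        assert np.allclose(inflate(m, 1.0), m)

    def test_inflate_hand_worked(self):
        col = np.array([[0.8], [0.2]])
        out = inflate(col, 2.0)
        assert np.allclose(out[:, 0], [0.64 / 0.68, 0.04 / 0.68])

    def test_inflate_symmetric_column_unchanged(self):
        col = np.array([[0.5], [0.5]])
        assert np.allclose(inflate(col, 2.0), col)

    def test_penalty_identity_on_fresh_record(self, rng):
        m = rng.random((3, 3))
        m /= m.sum(axis=0)
        out = apply_penalty(m, MCLParams(), AttractorRecord(), ["A", "B", "C"])
        assert np.array_equal(out, m)

    def test_penalty_scales_then_renormalizes(self):
        m = np.array([[0.5, 0.8], [0.5, 0.2]])
        rec = AttractorRecord(counts={"A": 1})
        out = apply_penalty(m, MCLParams(pp=1.25, b=0.5), rec, ["A", "B"])
        # column A scaled by 1/1.25 then renormalized -> unchanged ratios in column
        assert np.allclose(out.sum(axis=0), 1.0)
        assert np.allclose(out[:, 1], m[:, 1])

    def test_penalty_exponent_counts_pow_b(self):
        # counts=4, b=0.5 -> exponent 2 -> scale 1/1.5625
        rec = AttractorRecord(counts={"A": 4})
        m = np.array([[1.0]])
        scaled = np.power(1.25, -np.power(4.0, 0.5))
        assert scaled == pytest.approx(1 / 1.5625)
        out = apply_penalty(m, MCLParams(pp=1.25, b=0.5), rec, ["A"])
        assert np.allclose(out, 1.0)  # single entry renormalizes back

    def test_prune_restores_dead_column(self):
        m = np.array([[1 - 1e-9, 0.5], [1e-9, 0.5]])
        out = prune(m, 1e-6)
        assert out[1, 0] == 0.0 and out[0, 0] == 1.0
        assert np.allclose(out.sum(axis=0), 1.0)


def brute_mcl_matrix(net, params, counts=None):
    """Independent plain-loop iteration of the penalty/expand/inflate/prune sequence."""
    order = sorted(net.nodes)
    n = len(order)
    idx = {u: i for i, u in enumerate(order)}
    adj = np.zeros((n, n))
    for u, v in net.graph.edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = net.weight(u, v)
    for i in range(n):
        mx = adj[i].max()
        adj[i, i] = mx if mx > 0 else 1.0
    mat = adj / adj.sum(axis=0)
    counts = counts or {}
    for _ in range(params.max_iter):
        cur = mat.copy()
        for j, node in enumerate(order):  # penalty, column by column
            c = counts.get(node, 0)
            if c:
                cur[:, j] *= params.pp ** -(c ** params.b)
        cur /= cur.sum(axis=0)
        nxt = np.zeros_like(cur)  # expansion by explicit loops
        for i in range(n):
            for j in range(n):
                nxt[i, j] = sum(cur[i, k] * cur[k, j] for k in range(n))
        nxt = nxt ** params.ic  # inflation
        nxt /= nxt.sum(axis=0)
        nxt[nxt < params.prune_eps] = 0.0
        for j in range(n):
            if nxt[:, j].sum() == 0:
                nxt[j, j] = 1.0
        nxt /= nxt.sum(axis=0)
        if np.abs(nxt - mat).max() < params.tol:
            return nxt, order
        mat = nxt
    return mat, order


def clusters_from_matrix(mat, order):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(i for i in range(len(order)) if mat[i, i] > 0)
    for i in list(g.nodes):
        for j in np.nonzero(mat[i, :] > 0)[0]:
            g.add_edge(i, int(j))
    return sorted(
        (frozenset(order[i] for i in comp) for comp in nx.connected_components(g)),
        key=lambda c: (-len(c), min(c)),
    )


class TestRunMCL:
    def test_two_disjoint_triangles(self):
        net = PPINetwork.from_edges(triangle("x") + triangle("y"))
        clusters = run_mcl(net, MCLParams(ic=2.0))
        assert sorted(clusters, key=min) == [
            frozenset({"xA", "xB", "xC"}),
            frozenset({"yA", "yB", "yC"}),
        ]

    def test_k4_single_cluster(self):
        net = PPINetwork.from_edges(
            [(a, b) for i, a in enumerate("ABCD") for b in "ABCD"[i + 1:]]
        )
        assert run_mcl(net, MCLParams(ic=2.0)) == [frozenset("ABCD")]

    def test_matches_brute_force_matrix_and_clusters(self, rng):
        for _ in range(10):
            net = random_network(rng, n_max=12)
            params = MCLParams(ic=float(rng.uniform(1.2, 4.0)))
            expected_mat, order = brute_mcl_matrix(net, params)
            got = run_mcl(net, params)
            assert got == clusters_from_matrix(expected_mat, order)

    def test_brute_force_matrix_agreement_on_triangles(self):
        net = PPINetwork.from_edges(triangle("x") + triangle("y"))
        params = MCLParams(ic=2.0)
        expected, order = brute_mcl_matrix(net, params)
        from dyncomplex.mcl import build_adjacency as ba, normalize as nm
        import dyncomplex.mcl as mclmod

        fm = nm(ba(net))
        mat = fm.mat
        rec = AttractorRecord()
        for _ in range(params.max_iter):
            new = mclmod.apply_penalty(mat, params, rec, fm.order)
            new = mclmod.expand(new)
            new = mclmod.inflate(new, params.ic)
            new = mclmod.prune(new, params.prune_eps)
            if np.abs(new - mat).max() < params.tol:
                mat = new
                break
            mat = new
        assert np.allclose(mat, expected, atol=1e-8)

    def test_isolated_nodes_become_singletons(self):
        net = PPINetwork.from_edges([], nodes=["A", "B", "C"])
        assert run_mcl(net, MCLParams()) == [
            frozenset({"A"}), frozenset({"B"}), frozenset({"C"})
        ]

    def test_no_cluster_spans_components(self, rng):
        import networkx as nx

        for _ in range(10):
            net = random_network(rng, n_max=15, p=0.2)
            comp_of = {}
            for k, comp in enumerate(nx.connected_components(net.graph)):
                for node in comp:
                    comp_of[node] = k
            for cluster in run_mcl(net, MCLParams(ic=2.0)):
                assert len({comp_of[n] for n in cluster}) == 1

    def test_deterministic(self, rng):
        net = random_network(rng, n_max=20)
        assert run_mcl(net, MCLParams(ic=2.5)) == run_mcl(net, MCLParams(ic=2.5))

    def test_relabeling_invariance(self):
        net1 = PPINetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        net2 = PPINetwork.from_edges(
            [(mapping[u], mapping[v]) for u, v in [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")]]
        )
        c1 = run_mcl(net1, MCLParams(ic=2.0))
        c2 = run_mcl(net2, MCLParams(ic=2.0))
        assert [frozenset(mapping[n] for n in c) for c in c1] == c2

    def test_attractor_record_incremented(self):
        net = PPINetwork.from_edges(triangle())
        rec = AttractorRecord()
        run_mcl(net, MCLParams(ic=2.0), rec)
        assert sum(rec.counts.values()) >= 1


class TestFilterMinSize:
    @pytest.mark.parametrize(
        "clusters,expected_kept",
        [
            ([frozenset("AB")], []),
            ([frozenset("ABC")], [frozenset("ABC")]),
            (
                [frozenset("ABCDE"), frozenset("FG"), frozenset("HIJ"), frozenset("K")],
                [frozenset("ABCDE"), frozenset("HIJ")],
            ),
        ],
    )
    def test_filtering(self, clusters, expected_kept):
        kept, noise = filter_min_size(clusters, 3)
        assert kept == expected_kept
        assert noise == set().union(*(c for c in clusters if len(c) < 3)) - set().union(
            set(), *expected_kept
        )
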