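"""Graphical lasso networks, StARS, covariate stripping, module statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decnet import (
    connectedness_test,
    edge_enrichment,
    fit_ggm,
    neighbor_subgraph,
    partial_correlations,
    stars_select,
    strip_covariate_nodes,
    strong_edges,
)
from decnet.network import GGMNetwork, fit_ggm_data
from decnet.simulate import simulate_purity_confounding


def _net_from_weights(weights, extra_nodes=0):
    """Build a network whose edge list carries exactly the given weights."""
    m = len(weights)
    p = m + 1 + extra_nodes
    pcor = np.eye(p)
    adj = np.zeros((p, p), dtype=bool)
    theta = np.eye(p)
    for e, w in enumerate(weights):  # star graph: node 0 to nodes 1..m
        pcor[0, e + 1] = pcor[e + 1, 0] = w
        adj[0, e + 1] = adj[e + 1, 0] = True
        theta[0, e + 1] = theta[e + 1, 0] = -w
    names = [f"n{i}" for i in range(p)]
    return GGMNetwork(names, np.zeros(p, bool), 0.1, theta, pcor, adj)


def _graph_net(g):
    import networkx as nx

    p = g.number_of_nodes()
    adj = nx.to_numpy_array(g, dtype=bool)
    return GGMNetwork(
        [f"g{i}" for i in range(p)], np.zeros(p, bool), 0.1, np.eye(p), np.eye(p), adj
    )


def test_partial_correlation_closed_form():
    theta = np.array([[2.0, -1.0], [-1.0, 2.0]])
    rho = partial_correlations(theta)
    assert rho[0, 1] == pytest.approx(0.5)
    assert rho[0, 0] == 1.0


def test_partial_correlation_matches_inversion_oracle():
    """rho from theta equals the normalized negative inverse covariance (p <= 8)."""
    rng = np.random.default_rng(0)
    for p in (3, 5, 8):
        A = rng.normal(size=(p, p))
        theta = A @ A.T + p * np.eye(p)
        sigma = np.linalg.inv(theta)
        rho = partial_correlations(theta)
        # oracle: invert sigma independently and normalize
        theta_back = np.linalg.inv(sigma)
        d = np.sqrt(np.diag(theta_back))
        oracle = -theta_back / np.outer(d, d)
        np.fill_diagonal(oracle, 1.0)
        assert np.abs(rho - oracle).max() < 1e-10


def test_independent_variables_give_empty_graph():
    rng = np.random.default_rng(1)
    data = pd.DataFrame(rng.standard_normal((10, 500)),
                        index=[f"v{i}" for i in range(10)])
    net = fit_ggm_data(data, lam=0.5)
    assert net.n_edges == 0


def test_ggm_log_transform_and_covariate_flags():
    rng = np.random.default_rng(2)
    n = 60
    G = pd.DataFrame(rng.lognormal(2, 0.5, (5, n)),
                     index=[f"g{i}" for i in range(5)],
                     columns=[f"s{i}" for i in range(n)])
    P = pd.DataFrame(rng.dirichlet([2, 2], size=n).T, index=["cancer", "stroma"],
                     columns=G.columns)
    net = fit_ggm(G, list(G.index), P, lam=0.3)
    assert net.n_nodes == 7
    assert net.covariate_mask.sum() == 2
    assert [n for n, c in zip(net.node_names, net.covariate_mask) if c] == ["cancer", "stroma"]
    # theta symmetric positive definite, unit-diagonal pcor
    assert np.all(np.linalg.eigvalsh(net.theta) > 0)
    np.testing.assert_allclose(net.pcor.diagonal(), 1.0)


def test_strip_covariates_no_refit_idempotent():
    rng = np.random.default_rng(3)
    n = 80
    G = pd.DataFrame(rng.lognormal(2, 0.4, (6, n)),
                     index=[f"g{i}" for i in range(6)],
                     columns=[f"s{i}" for i in range(n)])
    P = pd.DataFrame(rng.dirichlet([2, 2, 2, 2], size=n).T,
                     index=["a", "b", "c", "d"], columns=G.columns)
    net = fit_ggm(G, list(G.index), P, lam=0.2)
    stripped = strip_covariate_nodes(net)
    assert stripped.n_nodes == net.n_nodes - 4
    assert not stripped.covariate_mask.any()
    # gene-gene entries are bit-identical (no refit)
    gene_idx = np.nonzero(~net.covariate_mask)[0]
    np.testing.assert_array_equal(
        stripped.pcor, net.pcor[np.ix_(gene_idx, gene_idx)]
    )
    with pytest.warns(UserWarning, match="no covariate nodes"):
        twice = strip_covariate_nodes(stripped)
    np.testing.assert_array_equal(twice.adjacency, stripped.adjacency)


def test_strong_edge_rule_reproduces_reference_arithmetic():
    """mu = -0.00492, sigma = 0.0297: only edges above 0.02478 are strong."""
    rng = np.random.default_rng(4)
    w = rng.normal(0, 1, 40)
    w = (w - w.mean()) / w.std(ddof=1)  # exact sample mean 0, sd 1
    weights = -0.00492 + 0.0297 * w
    net = _net_from_weights(list(weights))
    mu, sigma = net.edge_weight_stats()
    assert mu == pytest.approx(-0.00492, abs=1e-12)
    assert sigma == pytest.approx(0.0297, abs=1e-12)
    strong = strong_edges(net)
    threshold = -0.00492 + 0.0297
    assert threshold == pytest.approx(0.02478)
    expected = {f"n{i + 1}" for i, wt in enumerate(weights) if wt > threshold}
    assert set(strong["node_b"]) | set(strong["node_a"]) - {"n0"} == expected
    assert (strong["weight"] > threshold).all()
    # classification arithmetic on the reference constants
    assert 0.03 > threshold
    assert -0.01 <= threshold


def test_strong_edges_degenerate_and_monotone():
    flat = _net_from_weights([0.2, 0.2, 0.2])
    assert len(strong_edges(flat)) == 0  # sigma = 0, nothing exceeds mu

    rng = np.random.default_rng(5)
    net = _net_from_weights(list(rng.normal(0, 0.05, 30)))
    s1 = strong_edges(net, n_sd=1)
    s2 = strong_edges(net, n_sd=2)
    pairs = lambda df: {tuple(sorted(t)) for t in zip(df["node_a"], df["node_b"])}
    assert pairs(s2) <= pairs(s1)

    single = _net_from_weights([0.5])
    with pytest.warns(UserWarning, match="fewer than 2"):
        assert len(strong_edges(single)) == 0


def test_edge_count_monotone_along_penalty_path():
    rng = np.random.default_rng(6)
    p, n = 12, 300
    A = rng.normal(size=(p, p))
    cov = A @ A.T / p + np.eye(p)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n).T
    data = pd.DataFrame(X, index=[f"v{i}" for i in range(p)])
    counts = [fit_ggm_data(data, lam).n_edges for lam in (0.6, 0.4, 0.2, 0.1)]
    assert counts == sorted(counts)


def test_stars_on_independent_variables_selects_sparse_graph():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(rng.standard_normal((15, 200)),
                        index=[f"v{i}" for i in range(15)])
    lam, instab = stars_select(data, np.geomspace(0.6, 0.05, 8), seed=8)
    net = fit_ggm_data(data, lam)
    n_pairs = 15 * 14 / 2
    assert net.n_edges <= 0.01 * n_pairs + 1


def test_covariate_nodes_suppress_purity_confounded_edge():
    """The spurious composition-driven edge vanishes when proportions are nodes."""
    present_without, present_with = 0, 0
    for seed in range(10):
        G, P, a, b = simulate_purity_confounding(seed=seed)
        no_cov = fit_ggm(G, list(G.index), P=None, lam=0.2)
        with_cov = strip_covariate_nodes(fit_ggm(G, list(G.index), P, lam=0.2))
        edge = lambda net: bool(net.adjacency[net.node_index(a), net.node_index(b)])
        present_without += edge(no_cov)
        present_with += edge(with_cov)
    assert present_without >= 9
    assert present_with <= 1


def test_connectedness_planted_clique_significant():
    import networkx as nx

    g = nx.erdos_renyi_graph(50, 0.05, seed=42)
    for i in range(5):
        for j in range(i + 1, 5):
            g.add_edge(i, j)
    net = _graph_net(g)
    res = connectedness_test(net, [f"g{i}" for i in range(5)], n_perm=10_000, seed=1)
    assert res.observed == 10
    assert res.p <= 0.01


def test_connectedness_null_p_is_uniform():
    """p-values for random node sets pass a KS test against Uniform(0,1)."""
    import networkx as nx

    g = nx.erdos_renyi_graph(50, 0.15, seed=7)
    net = _graph_net(g)
    rng = np.random.default_rng(9)
    ps = []
    for t in range(100):
        nodes = rng.choice(50, size=21, replace=False)
        ps.append(
            connectedness_test(net, [f"g{i}" for i in nodes], n_perm=2000, seed=100 + t).p
        )
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_connectedness_empty_induced_subgraph():
    import networkx as nx

    g = nx.empty_graph(20)
    g.add_edge(10, 11)
    net = _graph_net(g)
    res = connectedness_test(net, ["g0", "g1", "g2"], n_perm=1000, seed=0)
    assert res.observed == 0
    assert res.p == pytest.approx(1.0, abs=1 / 1001)


def test_edge_enrichment_matches_hypergeometric_example():
    """Degree-4 node with 3 of its neighbors in a 5-gene target on 21 nodes."""
    import networkx as nx

    g = nx.empty_graph(21)
    for j in (1, 2, 3, 4):
        g.add_edge(0, j)
    net = _graph_net(g)
    target = ["g1", "g2", "g3", "g10", "g11"]
    res = edge_enrichment(net, "g0", target)
    assert res.overlap == 3
    assert res.p == pytest.approx(155 / 4845, abs=1e-10)

    assert edge_enrichment(net, "g0", [f"g{i}" for i in range(1, 21)]).p == pytest.approx(1.0)
    assert edge_enrichment(net, "g0", []).p == pytest.approx(1.0)
    assert edge_enrichment(net, "g5", target).p == pytest.approx(1.0)  # degree 0


def test_neighbor_subgraph_orders():
    import networkx as nx

    g = nx.path_graph(4)  # g0 - g1 - g2 - g3
    net = _graph_net(g)
    sub1 = neighbor_subgraph(net, "g1", order=1)
    assert set(sub1.node_names) == {"g0", "g1", "g2"}
    assert sub1.n_edges == 2
    assert neighbor_subgraph(net, "g1", order=0).node_names == ["g1"]
    assert set(neighbor_subgraph(net, "g1", order=10).node_names) == {"g0", "g1", "g2", "g3"}
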