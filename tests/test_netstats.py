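"""Node statistics, transitivity, the power mixed model and keystones."""

import networkx as nx
import numpy as np
import pytest

from cooccurnet import (
    CooccurrenceNetwork,
    fit_power_mixed,
    node_stats,
    rank_keystones,
    transitivity,
)
from cooccurnet.netstats import NodeStats


def _net(edges, eco="E1"):
    g = nx.Graph()
    g.add_edges_from(edges)
    return CooccurrenceNetwork(eco, "positive", g)


def _stats_dict(net):
    return {s.taxon: s for s in node_stats(net)}


def test_star_centrality_closed_form():
    s = _stats_dict(_net([("c", "l1"), ("c", "l2"), ("c", "l3")]))
    assert s["c"].degree_norm == pytest.approx(1.0)
    assert s["c"].betweenness == pytest.approx(3.0)  # C(3,2) leaf pairs
    for leaf in ("l1", "l2", "l3"):
        assert s[leaf].degree_norm == pytest.approx(1 / 3)
        assert s[leaf].betweenness == pytest.approx(0.0)


def test_path_middle_node_betweenness():
    s = _stats_dict(_net([("a", "b"), ("b", "c")]))
    assert s["b"].betweenness == pytest.approx(1.0)


def test_complete_graph_has_zero_betweenness():
    import itertools

    s = _stats_dict(_net(list(itertools.combinations("abcd", 2))))
    assert all(v.betweenness == 0 for v in s.values())
    assert all(v.degree_norm == 1.0 for v in s.values())


def test_degree_sum_equals_twice_edges():
    g = nx.relabel_nodes(nx.gnp_random_graph(15, 0.3, seed=4), str)
    net = CooccurrenceNetwork("E1", "positive", g)
    stats = node_stats(net)
    n = g.number_of_nodes()
    total_degree = sum(s.degree_norm * (n - 1) for s in stats)
    assert total_degree == pytest.approx(2 * g.number_of_edges())


@pytest.mark.parametrize(
    "edges,expected",
    [
        ([("a", "b"), ("b", "c"), ("a", "c")], 1.0),                 # triangle
        ([("c", "l1"), ("c", "l2"), ("c", "l3")], 0.0),              # star
        ([("a", "b"), ("b", "c"), ("a", "c"), ("c", "p")], 0.6),     # 3/5 triples
    ],
)
def test_transitivity_closed_forms(edges, expected):
    summary = transitivity(_net(edges))
    assert summary.clustering_coefficient == pytest.approx(expected)


def test_small_world_flag_compares_to_random_expectation():
    tri = transitivity(_net([("a", "b"), ("b", "c"), ("a", "c")]))
    assert tri.random_expectation == pytest.approx(2 / 3)
    assert tri.small_world  # 1.0 > 2/3
    star = transitivity(_net([("c", "l1"), ("c", "l2"), ("c", "l3")]))
    assert not star.small_world


def make_power_stats(beta, alpha=2.0, sigma=0.0, rep_offsets=(0.0, 0.0),
                     n_per_rep=30, seed=0, eco="E1", level=0.5):
    rng = np.random.default_rng(seed)
    out = []
    for r, off in enumerate(rep_offsets):
        deg = rng.uniform(0.05, 1.0, n_per_rep)
        bet = alpha * deg**beta * np.exp(off + sigma * rng.standard_normal(n_per_rep))
        out += [
            NodeStats(f"T{i}", eco, f"R{r + 1}", float(d), float(b), level)
            for i, (d, b) in enumerate(zip(deg, bet))
        ]
    return out


def test_noiseless_power_law_recovered_exactly():
    fit = fit_power_mixed(make_power_stats(beta=3.0, alpha=2.0), "E1", 0.5)
    assert fit.alpha == pytest.approx(2.0, abs=1e-6)
    assert fit.beta == pytest.approx(3.0, abs=1e-6)
    assert fit.n_obs == 60


def test_replicate_intercepts_recovered():
    fit = fit_power_mixed(
        make_power_stats(beta=2.0, rep_offsets=(0.2, -0.2)), "E1", 0.5
    )
    assert fit.beta == pytest.approx(2.0, abs=1e-4)
    assert fit.random_intercepts["R1"] == pytest.approx(0.2, abs=0.02)
    assert fit.random_intercepts["R2"] == pytest.approx(-0.2, abs=0.02)


def test_zero_betweenness_nodes_are_excluded_not_fit():
    stats = make_power_stats(beta=1.5, sigma=0.1, rep_offsets=(0.1, -0.1))
    stats.append(NodeStats("Tzero", "E1", "R1", 0.4, 0.0, 0.5))
    fit = fit_power_mixed(stats, "E1", 0.5)
    assert fit.n_excluded_zero == 1
    assert fit.n_obs == 60


def test_degenerate_all_zero_betweenness_rejected():
    stats = [NodeStats(f"T{i}", "E1", "R1", 0.5, 0.0, 0.5) for i in range(10)]
    with pytest.raises(ValueError, match="degenerate"):
        fit_power_mixed(stats, "E1", 0.5)


def test_keystone_ranking_monotone_and_sized():
    stats = make_power_stats(beta=2.0, sigma=0.2, rep_offsets=(0.1, -0.1), seed=3)
    fit = fit_power_mixed(stats, "E1", 0.5)
    assert fit.beta > 0
    top3 = rank_keystones(fit, stats, 3)
    assert len(top3) == 3
    # with beta > 0 the ranking follows mean degree_norm
    mean_deg = {}
    for s in stats:
        mean_deg.setdefault(s.taxon, []).append(s.degree_norm)
    order = sorted(mean_deg, key=lambda t: -np.mean(mean_deg[t]))
    assert [t for t, _ in top3] == order[:3]
    preds = [p for _, p in top3]
    assert preds == sorted(preds, reverse=True)


def test_keystone_tie_broken_by_observed_betweenness():
    stats = [
        NodeStats("low", "E1", "R1", 0.5, 1.0, 0.5),
        NodeStats("high", "E1", "R1", 0.5, 9.0, 0.5),
        NodeStats("other", "E1", "R1", 0.25, 0.5, 0.5),
    ]
    fit_stub = __import__("cooccurnet").PowerFit(
        alpha=2.0, beta=1.0, beta_p=0.01, random_intercepts={}, n_obs=3,
        ecosystem="E1", level=0.5,
    )
    ranked = rank_keystones(fit_stub, stats, 2)
    assert [t for t, _ in ranked] == ["high", "low"]


def test_keystone_k_larger_than_taxa_returns_all():
    stats = [NodeStats("a", "E1", "R1", 0.5, 1.0, 0.5),
             NodeStats("b", "E1", "R1", 0.2, 0.5, 0.5)]
    fit_stub = __import__("cooccurnet").PowerFit(
        alpha=1.0, beta=1.0, beta_p=0.5, random_intercepts={}, n_obs=2,
        ecosystem="E1", level=0.5,
    )
    assert len(rank_keystones(fit_stub, stats, 10)) == 2
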