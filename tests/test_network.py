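import networkx as nx
import numpy as np
import pandas as pd
import pytest

import fruitset_wcna as fw
from fruitset_wcna.network import EdgelessGraphError, NetworkError

from oracles import naive_greedy_partition, random_connected_graph


def _corr_df(arr, ids=None):
    ids = ids or [f"f{i}" for i in range(len(arr))]
    return pd.DataFrame(np.asarray(arr, dtype=float), index=ids, columns=ids)


# ---------------------------------------------------------------- correlation

def test_correlation_identical_and_negated_rows():
    base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    df = pd.DataFrame([base, base, -base], index=["a", "b", "c"])
    r = fw.correlation_matrix(df)
    assert r.at["a", "b"] == pytest.approx(1.0, abs=1e-12)
    assert r.at["a", "c"] == pytest.approx(-1.0, abs=1e-12)


def test_correlation_matches_bruteforce_oracle():
    rng = np.random.default_rng(8)
    arr = rng.normal(size=(50, 12))
    df = pd.DataFrame(arr, index=[f"f{i}" for i in range(50)])
    r = fw.correlation_matrix(df)
    for i, j in [(0, 1), (3, 40), (17, 17), (49, 5)]:
        x, y = arr[i], arr[j]
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r.iloc[i, j] == pytest.approx(num / den, abs=1e-12)


def test_correlation_drops_zero_variance_feature():
    df = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]], index=["flat", "ok"])
    r = fw.correlation_matrix(df)
    assert "flat" not in r.index
    assert "ok" in r.index


# ---------------------------------------------------------------- thresholding

def test_build_network_tau_validation():
    r = _corr_df([[1.0, 0.5], [0.5, 1.0]])
    with pytest.raises(NetworkError):
        fw.build_network(r, tau=0.0)
    with pytest.raises(NetworkError):
        fw.build_network(r, tau=1.5)


def test_build_network_edge_criterion_and_isolates():
    # hand-set correlations straddling tau = 0.8; negative r counts via |r|
    r = _corr_df([[1.0, 0.85, -0.9, 0.2],
                  [0.85, 1.0, 0.79, 0.1],
                  [-0.9, 0.79, 1.0, -0.05],
                  [0.2, 0.1, -0.05, 1.0]])
    net = fw.build_network(r, tau=0.8)
    assert set(map(frozenset, net.graph.edges)) == {frozenset({"f0", "f1"}), frozenset({"f0", "f2"})}
    assert net.n_nodes == 4  # isolated f3 retained
    assert net.graph["f0"]["f2"]["weight"] == pytest.approx(0.9)


def test_build_network_extremes():
    rng = np.random.default_rng(9)
    arr = rng.uniform(-0.5, 0.5, size=(6, 6))
    arr = (arr + arr.T) / 2
    np.fill_diagonal(arr, 1.0)
    none = fw.build_network(_corr_df(arr), tau=0.999)
    assert none.n_edges == 0
    full = fw.build_network(_corr_df(arr), tau=1e-9)
    assert full.n_edges == 6 * 5 // 2


def test_network_monotone_in_tau():
    rng = np.random.default_rng(10)
    arr = rng.uniform(-1, 1, size=(10, 10))
    arr = (arr + arr.T) / 2
    np.fill_diagonal(arr, 1.0)
    r = _corr_df(arr)
    e_low = set(map(frozenset, fw.build_network(r, tau=0.3).graph.edges))
    e_high = set(map(frozenset, fw.build_network(r, tau=0.6).graph.edges))
    assert e_high <= e_low


# ---------------------------------------------------------------- modularity

def test_modularity_whole_graph_single_module_is_zero():
    g = nx.path_graph(5)
    q = fw.modularity(g, {n: "M1" for n in g.nodes})
    assert q == pytest.approx(0.0, abs=1e-12)


def test_modularity_two_disconnected_triangles():
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    assignment = {n: ("A" if n < 3 else "B") for n in g.nodes}
    assert fw.modularity(g, assignment) == pytest.approx(0.5, abs=1e-15)


def test_modularity_requires_full_assignment_and_edges():
    g = nx.Graph([(0, 1)])
    with pytest.raises(NetworkError, match="without module"):
        fw.modularity(g, {0: "A"})
    empty = nx.Graph()
    empty.add_nodes_from([0, 1])
    with pytest.raises(EdgelessGraphError):
        fw.modularity(empty, {0: "A", 1: "A"})


def test_modularity_agrees_with_networkx():
    rng = np.random.default_rng(11)
    for _ in range(20):
        g = random_connected_graph(rng)
        labels = {n: f"C{rng.integers(0, 3)}" for n in g.nodes}
        communities = {}
        for n, lab in labels.items():
            communities.setdefault(lab, set()).add(n)
        expected = nx.algorithms.community.modularity(g, communities.values(), weight=None)
        assert fw.modularity(g, labels) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- fast greedy

def test_fast_greedy_two_cliques():
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    part = fw.fast_greedy_modules(g)
    assert part.n_modules == 2
    assert part.q == pytest.approx(0.5, abs=1e-12)
    sizes = sorted(len(ms) for ms in part.module_members.values())
    assert sizes == [5, 5]


def test_fast_greedy_rejects_edgeless():
    g = nx.Graph()
    g.add_nodes_from("abc")
    with pytest.raises(EdgelessGraphError, match="tau"):
        fw.fast_greedy_modules(g)


def test_fast_greedy_matches_naive_oracle_on_small_graphs():
    rng = np.random.default_rng(12)
    for _ in range(60):
        g = random_connected_graph(rng)
        part = fw.fast_greedy_modules(g)
        got = {frozenset(map(str, ms)) for ms in part.module_members.values()}
        expected, q_expected = naive_greedy_partition(g)
        assert got == expected
        assert part.q == pytest.approx(float(q_expected), abs=1e-12)


def test_fast_greedy_label_order_invariance():
    rng = np.random.default_rng(13)
    g = random_connected_graph(rng)
    part1 = fw.fast_greedy_modules(g)
    shuffled = nx.Graph()
    edges = list(g.edges)
    rng.shuffle(edges)
    shuffled.add_nodes_from(sorted(g.nodes, reverse=True))
    shuffled.add_edges_from(edges)
    part2 = fw.fast_greedy_modules(shuffled)
    as_sets = lambda p: {frozenset(ms) for ms in p.module_members.values()}
    assert as_sets(part1) == as_sets(part2)
    assert part1.q == part2.q


def test_fast_greedy_beats_singletons_and_q_is_consistent():
    rng = np.random.default_rng(14)
    g = random_connected_graph(rng)
    part = fw.fast_greedy_modules(g)
    singletons = {n: str(n) for n in g.nodes}
    assert part.q >= fw.modularity(g, singletons)
    assert fw.modularity(g, part.assignment) == pytest.approx(part.q, abs=1e-12)


def test_module_labels_ordered_by_size():
    g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(3))
    part = fw.fast_greedy_modules(g)
    assert len(part.members("M1")) >= len(part.members("M2"))


# ---------------------------------------------------------------- hubs

def test_hub_ranking_star_graph():
    g = nx.star_graph(9)  # center 0, leaves 1..9
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    net = fw.CorrelationNetwork(g, tau=0.5)
    part = fw.fast_greedy_modules(g)
    hubs = fw.hub_ranking(net, part)
    assert hubs.iloc[0]["node"] == "n0"
    assert hubs.iloc[0]["degree"] == 9
    assert hubs["degree"].sum() == 2 * g.number_of_edges()  # handshake lemma


def test_hub_ranking_top_n_per_module():
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    net = fw.CorrelationNetwork(g, tau=0.5)
    part = fw.fast_greedy_modules(g)
    hubs = fw.hub_ranking(net, part, top_n=2)
    assert (hubs.groupby("module").size() == 2).all()
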