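"""Unsigned correlation networks and fast-greedy modularity modules.

The network is built by thresholding the absolute Pearson correlation
between feature profiles: an edge joins features i and j whenever
|r_ij| >= tau (default 0.8).  "Unsigned" means the sign of the correlation
is ignored — strongly anti-correlated features are linked too.

Modules are found with the agglomerative fast-greedy modularity
optimisation algorithm (Clauset–Newman–Moore): starting from singleton
communities, repeatedly merge the connected pair of communities giving the
largest modularity increase, and cut the merge dendrogram at the point of
maximum modularity Q.  Modularity uses the unweighted edge-count
formulation

    Q = sum_c ( e_cc - a_c^2 )

with e_cc the fraction of edges inside community c and a_c the fraction of
edge endpoints in c; a weighted variant (|r| edge weights) is selectable.
Ties in the merge gain are broken by the lexicographically smallest pair of
community representatives (a community's representative is its smallest
node id), which makes the result independent of input order.

Hubs are ranked by incident edge count (degree), the statistic used to name
the most connected genes of each module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import JointMatrix

log = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


class EdgelessGraphError(NetworkError):
    """No edge survived the threshold; lower tau and retry."""


@dataclass
class CorrelationNetwork:
    graph: nx.Graph            # nodes: feature ids; edge attr weight = |r|
    tau: float
    correlation_kind: str = "pearson"
    layers: pd.Series | None = None  # feature id -> layer tag

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ModulePartition:
    """node -> module label (M1..Mk, descending size), with the modularity
    score and the merge history that produced it."""

    assignment: dict            # node -> module label
    q: float
    merges: tuple = ()          # ((rep_a, rep_b, delta_q), ...)
    module_members: dict = field(default_factory=dict)  # label -> tuple of nodes

    def __post_init__(self) -> None:
        if not self.module_members:
            groups: dict[str, list] = {}
            for node, lab in self.assignment.items():
                groups.setdefault(lab, []).append(node)
            self.module_members = {lab: tuple(sorted(ms)) for lab, ms in groups.items()}

    @property
    def n_modules(self) -> int:
        return len(self.module_members)

    def n_modules_min_size(self, min_size: int = 2) -> int:
        """Module count ignoring tiny modules (isolated features retained
        by the network builder each form their own singleton module)."""
        return sum(1 for ms in self.module_members.values() if len(ms) >= min_size)

    def members(self, label: str) -> tuple:
        return self.module_members[label]


def correlation_matrix(m: JointMatrix | pd.DataFrame, kind: str = "pearson",
                       min_obs: int = 3) -> pd.DataFrame:
    """Feature x feature correlation over pairwise-complete columns.
    Zero-variance features are dropped with a warning; pairs with fewer
    than ``min_obs`` complete observations are left undefined (NaN)."""
    values = m.values if isinstance(m, JointMatrix) else m
    if values.shape[1] < 3:
        raise NetworkError("need at least 3 columns for correlations")
    if kind not in ("pearson", "spearman"):
        raise NetworkError(f"unknown correlation kind {kind!r}")
    sd = values.std(axis=1, ddof=1, skipna=True)
    degenerate = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(degenerate):
        log.warning("correlation_matrix: dropping %d zero-variance feature(s): %s",
                    len(degenerate), list(degenerate[:5]))
        values = values.drop(index=degenerate)
    r = values.T.corr(method=kind, min_periods=min_obs)
    np.fill_diagonal(r.values, 1.0)
    return r


def build_network(r: pd.DataFrame, tau: float = 0.8,
                  layers: pd.Series | None = None,
                  correlation_kind: str = "pearson") -> CorrelationNetwork:
    """Edge (i, j) iff |r_ij| >= tau (i != j); weight |r_ij|.  Isolated
    nodes are retained so module tables account for every selected
    feature."""
    if not (0.0 < tau <= 1.0):
        raise NetworkError("tau must be in (0, 1]")
    if r.shape[0] != r.shape[1] or not r.index.equals(r.columns):
        raise NetworkError("correlation matrix must be square with matching labels")
    g = nx.Graph()
    nodes = list(r.index)
    g.add_nodes_from(nodes)
    if layers is not None:
        nx.set_node_attributes(g, {n: str(layers[n]) for n in nodes if n in layers.index}, "layer")
    arr = np.abs(r.to_numpy(dtype=float))
    iu, ju = np.where(np.triu(arr >= tau, k=1))
    for i, j in zip(iu, ju):
        g.add_edge(nodes[i], nodes[j], weight=float(arr[i, j]))
    return CorrelationNetwork(g, tau, correlation_kind, layers)


# ---------------------------------------------------------------------------
# modularity


def modularity(net: CorrelationNetwork | nx.Graph, assignment: dict,
               weighted: bool = False) -> float:
    """Newman–Girvan modularity Q = sum_c (e_cc - a_c^2) of an assignment,
    on edge counts by default (edge weights when ``weighted``).  An
    edgeless graph has no defined Q and raises."""
    g = net.graph if isinstance(net, CorrelationNetwork) else net
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise NetworkError(f"nodes without module assignment: {missing[:5]}")
    if g.number_of_edges() == 0:
        raise EdgelessGraphError("modularity undefined on an edgeless graph")
    def w(u, v, d):
        return d.get("weight", 1.0) if weighted else 1.0
    m2 = sum(w(u, v, d) for u, v, d in g.edges(data=True)) * 2.0
    intra: dict = {}
    deg: dict = {}
    for u, v, d in g.edges(data=True):
        cu, cv = assignment[u], assignment[v]
        wt = w(u, v, d)
        deg[cu] = deg.get(cu, 0.0) + wt
        deg[cv] = deg.get(cv, 0.0) + wt
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + wt
    q = 0.0
    communities = set(assignment[n] for n in g.nodes)
    for c in communities:
        e_cc = intra.get(c, 0.0) / (m2 / 2.0)
        a_c = deg.get(c, 0.0) / m2
        q += e_cc - a_c * a_c
    return q


def fast_greedy_modules(net: CorrelationNetwork | nx.Graph,
                        weighted: bool = False) -> ModulePartition:
    """Agglomerative fast-greedy modularity optimisation.

    Starts with every node its own community; at each step merges the
    *connected* pair of communities with the largest modularity gain
    dQ = w_ij/m - 2 a_i a_j (ties: lexicographically smallest pair of
    community representatives); returns the partition at the dendrogram cut
    with maximum Q.  Module labels M1..Mk are assigned by descending module
    size, then by smallest member id.
    """
    g = net.graph if isinstance(net, CorrelationNetwork) else net
    if g.number_of_edges() == 0:
        raise EdgelessGraphError(
            "cannot detect modules in an edgeless network; lower the correlation threshold tau")
    nodes = sorted(g.nodes, key=str)

    def wt(d):
        return d.get("weight", 1.0) if weighted else 1

    # For the default unweighted Q everything below is integer arithmetic on
    # a common denominator 4*m^2 (Q = sum_c (4*m*intra_c - deg_c^2) / 4m^2;
    # merge gain dQ = (4*m*w_ij - 2*deg_i*deg_j) / 4m^2), so modularity
    # comparisons and tie-breaks are exact.  The weighted variant uses
    # floats.
    m_tot = sum(wt(d) for _, _, d in g.edges(data=True))
    denom = 4.0 * m_tot * m_tot
    members: dict[str, set] = {str(n): {n} for n in nodes}
    deg: dict[str, float] = {str(n): 0 for n in nodes}    # community degree sums
    intra: dict[str, float] = {str(n): 0 for n in nodes}
    between: dict[tuple, float] = {}
    for u, v, d in g.edges(data=True):
        cu, cv = str(u), str(v)
        w = wt(d)
        deg[cu] += w
        deg[cv] += w
        if cu == cv:
            continue
        key = (cu, cv) if cu < cv else (cv, cu)
        between[key] = between.get(key, 0) + w

    q_num = -sum(x * x for x in deg.values())  # all-singleton baseline (x 4m^2)
    best_num = q_num
    best_members = {rep: frozenset(ms) for rep, ms in members.items()}
    merges: list[tuple] = []

    while between:
        best_pair, best_dq = None, None
        for (ci, cj), w in between.items():
            dq = 4 * m_tot * w - 2 * deg[ci] * deg[cj]
            if best_dq is None or dq > best_dq or (dq == best_dq and (ci, cj) < best_pair):
                best_pair, best_dq = (ci, cj), dq
        ci, cj = best_pair                      # merge cj into ci (ci < cj)
        merges.append((ci, cj, best_dq / denom))
        q_num += best_dq
        intra[ci] = intra[ci] + intra[cj] + between.pop((ci, cj))
        deg[ci] += deg[cj]
        members[ci] |= members[cj]
        del members[cj], deg[cj], intra[cj]
        # re-key cj's remaining between-links onto ci
        for key in [k for k in between if cj in k]:
            other = key[0] if key[1] == cj else key[1]
            w = between.pop(key)
            nk = (ci, other) if ci < other else (other, ci)
            between[nk] = between.get(nk, 0) + w
        if q_num > best_num:
            best_num = q_num
            best_members = {rep: frozenset(ms) for rep, ms in members.items()}
    best_q = best_num / denom

    groups = sorted(best_members.values(), key=lambda ms: (-len(ms), min(map(str, ms))))
    assignment = {}
    module_members = {}
    for i, ms in enumerate(groups, start=1):
        label = f"M{i}"
        module_members[label] = tuple(sorted(ms, key=str))
        for n in ms:
            assignment[n] = label
    part = ModulePartition(assignment, best_q, tuple(merges), module_members)
    # internal consistency: stored Q must equal an independent recount
    check = modularity(g, assignment, weighted=weighted)
    if abs(check - best_q) > 1e-9:
        raise AssertionError(f"modularity bookkeeping drifted: {best_q} vs {check}")
    part.q = check
    return part


def hub_ranking(net: CorrelationNetwork, partition: ModulePartition | None = None,
                top_n: int | None = None) -> pd.DataFrame:
    """Per-node incident edge counts with module labels, sorted by
    descending degree then ascending node id.  ``top_n`` keeps the top rows
    per module (and the table remains globally sorted)."""
    g = net.graph
    rows = [(str(n), int(g.degree(n)),
             partition.assignment.get(n, "-") if partition else "-")
            for n in g.nodes]
    df = pd.DataFrame(rows, columns=["node", "degree", "module"])
    df = df.sort_values(["degree", "node"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    if top_n is not None:
        df = df.groupby("module", group_keys=False, sort=False).head(top_n).reset_index(drop=True)
    return df
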