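"""Independent reference implementations used only to check the package.

Everything here is deliberately naive and derived from first principles
(exact rational arithmetic, exhaustive enumeration, literal step-up loops)
so it shares no code path with the implementations under test.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np


def naive_greedy_partition(graph):
    """Agglomerative greedy modularity merging by full O(n^3) re-scan.

    Each step recomputes Q (exact rationals) for every candidate merge of
    two connected communities, takes the largest gain with ties broken by
    the lexicographically smallest pair of community representatives, and
    finally returns the earliest partition along the merge sequence with
    maximum Q.  Returns (set of frozensets, Q as Fraction).
    """
    m = graph.number_of_edges()
    edges = [(str(u), str(v)) for u, v in graph.edges()]
    degree = {str(n): graph.degree(n) for n in graph.nodes}

    def q_of(comms: dict) -> Fraction:
        comm_of = {}
        for rep, ms in comms.items():
            for n in ms:
                comm_of[n] = rep
        intra: dict = {}
        for u, v in edges:
            if comm_of[u] == comm_of[v]:
                intra[comm_of[u]] = intra.get(comm_of[u], 0) + 1
        q = Fraction(0)
        for rep, ms in comms.items():
            d = sum(degree[n] for n in ms)
            q += Fraction(intra.get(rep, 0), m) - Fraction(d, 2 * m) ** 2
        return q

    cur = {str(n): frozenset({str(n)}) for n in graph.nodes}
    sequence = [dict(cur)]
    while True:
        comm_of = {n: rep for rep, ms in cur.items() for n in ms}
        connected = set()
        for u, v in edges:
            a, b = comm_of[u], comm_of[v]
            if a != b:
                connected.add((a, b) if a < b else (b, a))
        if not connected:
            break
        q_cur = q_of(cur)
        best_pair, best_dq = None, None
        for (a, b) in sorted(connected):
            trial = {rep: ms for rep, ms in cur.items() if rep not in (a, b)}
            trial[min(a, b)] = cur[a] | cur[b]
            dq = q_of(trial) - q_cur
            if best_dq is None or dq > best_dq:
                best_pair, best_dq = (a, b), dq
        a, b = best_pair
        merged = {rep: ms for rep, ms in cur.items() if rep not in (a, b)}
        merged[min(a, b)] = cur[a] | cur[b]
        cur = merged
        sequence.append(dict(cur))
    qs = [q_of(p) for p in sequence]
    best_idx = 0
    for i, q in enumerate(qs):
        if q > qs[best_idx]:
            best_idx = i
    best = sequence[best_idx]
    return {frozenset(ms) for ms in best.values()}, qs[best_idx]


def hypergeom_tail_by_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(at least k marked in a size-n draw) by enumerating all C(N, n)
    subsets of a universe whose first K items are marked."""
    marked = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x in marked) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_table(n: int, K: int, N: int):
    """P(X >= k) for every k in 0..min(n, K), from one exhaustive
    enumeration of all C(N, n) draws."""
    marked = set(range(K))
    kmax = min(n, K)
    counts = [0] * (kmax + 1)
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        counts[sum(1 for x in draw if x in marked)] += 1
    tails = []
    for k in range(kmax + 1):
        tails.append(sum(counts[k:]) / total)
    return tails


def bh_stepup(p):
    """Literal Benjamini–Hochberg step-up: sort, q(i) = min_{j>=i} p(j)*m/j,
    map back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 8):
    """A random connected unweighted graph with 2..max_nodes nodes."""
    import networkx as nx

    n = int(rng.integers(2, max_nodes + 1))
    while True:
        p = rng.uniform(0.25, 0.9)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        if g.number_of_edges() and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
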