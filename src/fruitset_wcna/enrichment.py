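"""Per-module GO-term overrepresentation.

One-sided hypergeometric test (Fisher exact upper tail): for a module of
``n`` annotated features of which ``k`` carry a term that ``K`` of the
``N``-feature universe carry, p = P(X >= k) with
X ~ Hypergeometric(N, K, n).  The universe is the annotated portion of the
analysed feature set (platform universe), not the whole genome.  BH
adjustment is pooled across every (module, term) test of a network and
terms are flagged significant at q < 0.05.
"""

from __future__ import annotations

from scipy.stats import hypergeom

import pandas as pd

from .io import GoAnnotation
from .network import ModulePartition
from .stats import bh_fdr

Q_SIGNIFICANT = 0.05


class EnrichmentError(ValueError):
    pass


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): the chance of drawing at
    least k marked items in n draws without replacement from a pool of N
    items of which K are marked."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise EnrichmentError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k > K:
        raise EnrichmentError(f"k={k} exceeds the number of marked items K={K}")
    if k == 0:
        return 1.0
    # survival function at k-1; scipy computes this stably in log space
    return float(hypergeom.sf(k - 1, N, K, n))


def module_enrichment(partition: ModulePartition, annotation: GoAnnotation,
                      universe=None, min_term_size: int = 3) -> pd.DataFrame:
    """Test every (module, eligible term) pair for overrepresentation.

    ``universe`` defaults to the annotated features among the partition's
    nodes.  A term is eligible when at least ``min_term_size`` universe
    features carry it.  Returns a table with columns module, go_id,
    go_name, k, n, K, N, p, q, significant; q is BH over all tests pooled.
    """
    nodes = set(partition.assignment)
    if universe is None:
        universe = nodes & annotation.features
    else:
        universe = set(universe)
    if not universe:
        raise EnrichmentError("empty annotation universe")
    N = len(universe)
    term_carriers: dict[str, set] = {}
    for fid in universe:
        for term in annotation.terms_of(fid):
            term_carriers.setdefault(term, set()).add(fid)
    eligible = {t: c for t, c in term_carriers.items() if len(c) >= min_term_size}
    rows = []
    for label in sorted(partition.module_members, key=lambda x: (len(x), x)):
        module_feats = set(partition.members(label)) & universe
        n = len(module_feats)
        for term in sorted(eligible):
            carriers = eligible[term]
            K = len(carriers)
            k = len(module_feats & carriers)
            p = hypergeom_upper_tail(k, n, K, N)
            rows.append((label, term, annotation.term_names.get(term, term), k, n, K, N, p))
    df = pd.DataFrame(rows, columns=["module", "go_id", "go_name", "k", "n", "K", "N", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    df["significant"] = df["q"] < Q_SIGNIFICANT
    return df
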