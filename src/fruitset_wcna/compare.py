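"""Cross-network comparison across genotype pairs or cultivars.

The networks of different mutant/wild-type pairs are built from different
samples (and for RNA-seq data, from different feature sets), so they can
only be compared through what they share: common nodes, common hub
features, module-membership overlap (Jaccard), and — biologically most
informative — GO terms significant in at least one module of *every*
network ("common modules", e.g. photosynthesis appearing in all mutants).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import Q_SIGNIFICANT
from .network import CorrelationNetwork, ModulePartition


class CompareError(ValueError):
    pass


def common_nodes(networks) -> set:
    """Features present in every network (set intersection)."""
    networks = list(networks)
    if len(networks) < 2:
        raise CompareError("need at least two networks to intersect")
    sets = [set(n.graph.nodes) if isinstance(n, CorrelationNetwork) else set(n) for n in networks]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def common_terms(enrichments, q_threshold: float = Q_SIGNIFICANT) -> set:
    """GO terms significant (q < threshold) in at least one module of every
    network's enrichment table."""
    per_network = []
    for df in enrichments:
        sig = set(df.loc[df["q"] < q_threshold, "go_id"])
        per_network.append(sig)
    if not per_network:
        return set()
    out = per_network[0]
    for s in per_network[1:]:
        out = out & s
    return out


def common_hubs(hub_tables, top_h: int = 20) -> set:
    """Features appearing in the global top-``top_h`` hub list of every
    network (tables are already degree-sorted)."""
    sets = [set(df.head(top_h)["node"]) for df in hub_tables]
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def module_similarity(p1: ModulePartition, p2: ModulePartition) -> pd.DataFrame:
    """Jaccard index |A & B| / |A | B| between every module pair of two
    partitions (possibly over different node sets)."""
    labels1 = sorted(p1.module_members)
    labels2 = sorted(p2.module_members)
    out = pd.DataFrame(0.0, index=labels1, columns=labels2)
    for a in labels1:
        sa = set(p1.members(a))
        for b in labels2:
            sb = set(p2.members(b))
            union = sa | sb
            out.at[a, b] = len(sa & sb) / len(union) if union else 0.0
    return out


@dataclass
class CrossNetworkSummary:
    network_ids: tuple
    common_nodes: set
    common_terms: set
    common_hubs: set
    module_similarity: dict  # (id_a, id_b) -> Jaccard DataFrame


def summarize(network_ids, networks, partitions, enrichments, hub_tables,
              top_h: int = 20) -> CrossNetworkSummary:
    ids = tuple(network_ids)
    sims = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sims[(a, b)] = module_similarity(partitions[a], partitions[b])
    return CrossNetworkSummary(
        ids,
        common_nodes([networks[i] for i in ids]),
        common_terms([enrichments[i] for i in ids]),
        common_hubs([hub_tables[i] for i in ids], top_h=top_h),
        sims,
    )
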