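"""Cross-network commonalities across the three mutant pairs.

Intersects the three per-pair networks from 02_networks.py: features in
every network, GO terms significant in at least one module of every
network ("common modules"), and features in every network's top-20 hub
list.  Writes results/compare/summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

import fruitset_wcna as fw
from fruitset_wcna import io as fio
from fruitset_wcna.network import CorrelationNetwork, ModulePartition

MUTANTS = ("iaa9", "della", "tap3")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--runs", type=Path, default=Path("results/mutants"))
    ap.add_argument("--out", type=Path, default=Path("results/compare"))
    ap.add_argument("--top-h", type=int, default=20)
    args = ap.parse_args()

    networks, partitions, enrichments, hub_tables = {}, {}, {}, {}
    for mut in MUTANTS:
        pdir = args.runs / f"pair_{mut}"
        g = fio.read_edgelist(pdir / "network_edges.tsv")
        mods = pd.read_csv(pdir / "modules.tsv", sep="\t", dtype=str)
        g.add_nodes_from(mods["node"])
        networks[mut] = CorrelationNetwork(g, tau=0.8)
        partitions[mut] = ModulePartition(dict(zip(mods["node"], mods["module"])), q=0.0)
        enrichments[mut] = pd.read_csv(pdir / "enrichment.tsv", sep="\t")
        hub_tables[mut] = pd.read_csv(pdir / "hubs.tsv", sep="\t", dtype={"node": str})

    summary = fw.summarize(MUTANTS, networks, partitions, enrichments, hub_tables,
                           top_h=args.top_h)
    rows = ([("common_node", n) for n in sorted(summary.common_nodes)]
            + [("common_term", t) for t in sorted(summary.common_terms)]
            + [("common_hub", h) for h in sorted(summary.common_hubs)])
    fio.write_table(pd.DataFrame(rows, columns=["kind", "feature"]), args.out / "summary.tsv")

    names = enrichments[MUTANTS[0]].set_index("go_id")["go_name"].to_dict()
    print(f"common nodes across the three networks: {len(summary.common_nodes)}")
    print("common GO terms (significant in every network):")
    for t in sorted(summary.common_terms):
        print(f"  {t}  {names.get(t, '')}")
    print(f"common top-{args.top_h} hubs: {sorted(summary.common_hubs) or 'none'}")


if __name__ == "__main__":
    main()
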