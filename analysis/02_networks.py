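"""Per-genotype-pair correlation networks, modules, hubs and GO enrichment.

For each mutant / wild-type pair: log2-transform, average replicates per
design cell, pick the top 600 transcripts + metabolites by mean absolute
deviation, build the unsigned |r| >= 0.8 network, partition it with the
fast-greedy modularity optimiser, rank hubs by edge count and test
per-module GO overrepresentation (hypergeometric, BH q < 0.05).

Reads results/data/ (from 01_simulate.py); writes per-pair tables under
results/mutants/pair_<mutant>/.
"""

import argparse
from pathlib import Path

import pandas as pd

import fruitset_wcna as fw
from fruitset_wcna import io as fio

PAIRS = (("iaa9", "MTJi"), ("della", "MTB"), ("tap3", "MTJt"))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/mutants"))
    ap.add_argument("--tau", type=float, default=0.8)
    ap.add_argument("--k", type=int, default=600)
    args = ap.parse_args()

    transcripts = fw.read_matrix(args.data / "transcripts.tsv", layer="transcript")
    metabolites = fw.read_matrix(args.data / "metabolites.tsv", layer="metabolite")
    design = fw.read_design(args.data / "design.tsv")
    annotation = fw.read_annotation(args.data / "annotation.tsv")
    cfg = fw.RunConfig(tau=args.tau, k=args.k)

    for pair in PAIRS:
        res = fw.analyze_pair(transcripts, metabolites, design, annotation, pair, cfg)
        pdir = args.out / f"pair_{pair[0]}"
        fio.write_edgelist(res.network.graph, pdir / "network_edges.tsv")
        fio.write_table(pd.DataFrame(
            [(n, res.partition.assignment[n]) for n in sorted(res.partition.assignment)],
            columns=["node", "module"]), pdir / "modules.tsv")
        fio.write_table(res.hubs, pdir / "hubs.tsv")
        fio.write_table(res.enrichment, pdir / "enrichment.tsv")
        top = res.hubs.iloc[0]
        sig = res.enrichment[res.enrichment["significant"]]
        print(f"{pair[0]:>6s}: {res.network.n_nodes} nodes, {res.network.n_edges} edges, "
              f"{res.partition.n_modules_min_size(5)} modules (>=5 nodes), "
              f"Q={res.partition.q:.3f}; top hub {top['node']} ({top['degree']} edges, "
              f"{top['module']}); {sig['go_id'].nunique()} GO terms enriched")


if __name__ == "__main__":
    main()
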