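"""Sample ordination (PCA) and FDR-tiered differential hormone testing.

PCA of the iaa9-pair joint transcript+metabolite matrix shows how samples
spread along fruit-development status (PC1).  Hormones are tested mutant
vs wild type per stage and treatment arm with Welch's t-test, BH-adjusted
across the contrast; tiers: * q < 0.05, ** q < 0.005.

Reads results/data/; writes results/stats/.
"""

import argparse
from pathlib import Path

import fruitset_wcna as fw
from fruitset_wcna import io as fio

PAIRS = (("iaa9", "MTJi"), ("della", "MTB"), ("tap3", "MTJt"))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()

    transcripts = fw.read_matrix(args.data / "transcripts.tsv", layer="transcript")
    metabolites = fw.read_matrix(args.data / "metabolites.tsv", layer="metabolite")
    hormones = fw.read_matrix(args.data / "hormones.tsv", layer="hormone")
    design = fw.read_design(args.data / "design.tsv")
    annotation = fw.read_annotation(args.data / "annotation.tsv")

    res = fw.analyze_pair(transcripts, metabolites, design, annotation, PAIRS[0], fw.RunConfig())
    pc = fw.pca(res.joint.values)
    fio.write_table(pc.scores.reset_index(names="sample"), args.out / "pca_scores.tsv")
    fio.write_table(pc.loadings.reset_index(names="feature"), args.out / "pca_loadings.tsv")
    frac = pc.explained_variance_fraction
    print(f"PCA (iaa9 pair): PC1 {frac[0]:.1%}, PC2 {frac[1]:.1%} of variance")

    import pandas as pd
    h_log = fw.log_transform(hormones, 1.0)
    tables = []
    for mut, wt in PAIRS:
        ids = set(design.samples_for(genotypes=(mut, wt)))
        sub = h_log.subset_samples([s for s in h_log.sample_ids if s in ids])
        tables.append(fw.differential_test(sub, design, "genotype", mut, wt))
    diff = pd.concat(tables, ignore_index=True)
    fio.write_table(diff, args.out / "differential_hormones.tsv")
    for tier_label in ("**", "*"):
        hits = diff[diff["tier"] == tier_label]
        summary = ", ".join(f"{r.feature_id}@{r.stratum} ({r.contrast.split(':')[1]})"
                            for r in hits.itertuples()) or "none"
        print(f"tier {tier_label:2s}: {len(hits):2d} (feature, stage) pairs — {summary}")


if __name__ == "__main__":
    main()
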