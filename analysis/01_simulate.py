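"""Generate the synthetic multi-omics fruit-set study.

Three parthenocarpic mutant / wild-type pairs (iaa9/MTJi, della/MTB,
tap3/MTJt) sampled at -2..8 days after flowering with pollinated (P) and
emasculated (E) arms; ~10,000 transcripts (n=3), 715 metabolites (n=5) and
42 hormones (n=3) per sample.  Planted ground truth: five transcript
modules (photosynthesis, cell cycle, cell wall, oxidoreductase, protein
kinase), two metabolite modules, two transcript hubs, and a ~100-fold
pollination-induced auxin/gibberellin spike specific to the iaa9 mutant.

Writes the abundance matrices, sample design and GO annotation under
results/data/.
"""

import argparse
from pathlib import Path

import fruitset_wcna as fw


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    spec = fw.default_study_spec(seed=args.seed)
    ds = fw.generate(spec)
    for layer, m in ds.matrices.items():
        fw.write_matrix(m, args.out / f"{layer}s.tsv")
        print(f"{layer:12s} {m.shape[0]:>6d} features x {m.shape[1]:>3d} samples")
    fw.write_design(ds.design, args.out / "design.tsv")
    fw.write_annotation(ds.annotation, args.out / "annotation.tsv")
    n_blocks = len(spec.planted_blocks)
    n_hubs = len(spec.planted_hubs)
    print(f"planted: {n_blocks} modules, {n_hubs} hubs, "
          f"{len(spec.differential_effects)} hormone effects -> {args.out}")


if __name__ == "__main__":
    main()
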