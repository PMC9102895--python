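# fruitset-wcna

Weighted correlation network analysis (WCNA) of multi-omics data from
early tomato fruit set.

Parthenocarpic tomato mutants set fruit without pollination. Comparing
such mutants with their wild types across the days around flowering —
with transcript, metabolite and hormone layers measured on the same
pistils — lets one ask which co-regulated gene/metabolite programmes
(photosynthesis, sugar metabolism, cell division, cell wall remodelling)
drive pollination-independent fruit growth. This package implements that
analysis as a tested, reusable pipeline for anyone working with
genotype × stage × treatment multi-omics designs:

1. **Joint feature selection.** Log₂-transformed, replicate-averaged
   abundances are ranked by mean absolute deviation
   (MAD(x) = mean |xᵢ − x̄|) and the top *K* = 600 transcripts +
   metabolites are kept and z-scored.
2. **Unsigned correlation network.** Nodes are the selected features;
   an edge joins *i, j* whenever |r(xᵢ, xⱼ)| ≥ τ (Pearson, default
   τ = 0.8).
3. **Fast-greedy modules.** A from-scratch Clauset–Newman–Moore
   agglomerative optimiser of Newman–Girvan modularity
   Q = Σ_c (e_cc − a_c²) merges communities by largest ΔQ (deterministic
   tie-breaks, exact integer arithmetic for the unweighted Q) and cuts
   the dendrogram at maximum Q; modules are labelled M1…Mk by size.
4. **Hubs.** Nodes ranked by incident edge count, per module and
   globally.
5. **GO enrichment.** One-sided hypergeometric test per (module, term)
   against the annotated platform universe, Benjamini–Hochberg FDR,
   significant at q < 0.05.
6. **Ordination & differential tiers.** PCA (SVD, deterministic signs)
   of the joint matrix; Welch's t per hormone per stage with BH-adjusted
   two-tier significance: `*` q < 0.05, `**` q < 0.005.
7. **Cross-network comparison.** Common nodes, common hubs, Jaccard
   module overlap, and "common modules" = GO terms significant in every
   genotype pair's network.

A synthetic-data generator (`fruitset_wcna.synthetic`) emulates the
full study design — three mutant/WT pairs, stages −2…8 DAF, pollinated/
emasculated arms, ~10,000 transcripts (n = 3), 715 metabolites (n = 5),
42 hormones (n = 3) — with *planted* correlation blocks, hub stars and
hormone effects, so every stage of the pipeline is verifiable against
known ground truth without any external data.

## Worked example

```sh
python analysis/01_simulate.py --seed 1 --out results/data
python analysis/02_networks.py --data results/data --out results/mutants
python analysis/03_ordination_differential.py --data results/data --out results/stats
python analysis/04_cultivar_rerun.py --seed 1 --out results/cultivar
python analysis/05_compare.py --runs results/mutants --out results/compare
```

which prints (seed 1):

```
  iaa9: 600 nodes, 20185 edges, 8 modules (>=5 nodes), Q=0.776; top hub T00071 (120 edges, M1); 5 GO terms enriched
 della: 600 nodes, 21090 edges, 8 modules (>=5 nodes), Q=0.762; top hub T00001 (119 edges, M1); 5 GO terms enriched
  tap3: 600 nodes, 19645 edges, 9 modules (>=5 nodes), Q=0.764; top hub T00008 (120 edges, M1); 5 GO terms enriched
PCA (iaa9 pair): PC1 31.2%, PC2 19.3% of variance
tier **:  1 (feature, stage) pairs — GA20@4/P (iaa9-vs-MTJi)
tier * :  7 (feature, stage) pairs — IAA@2/P (iaa9-vs-MTJi), GA1@2/P (iaa9-vs-MTJi), ...
common GO terms (significant in every network):
  GO:0007049  cell cycle
  GO:0015979  photosynthesis
  ...
```

Reading this: each mutant/WT pair yields a 600-feature network whose
modules recover the planted co-regulation blocks (the five planted
transcript programmes appear as significant GO terms in *every* pair's
network, hence "common modules"); the planted ~100-fold pollinated-`iaa9`
auxin/gibberellin spike is exactly the set of (hormone, stage) pairs the
tier test flags; and PC1 orders samples along fruit-development status.

The same steps run unchanged on a second, transcripts-only cultivar
design (`04_cultivar_rerun.py`), where the four planted modules surface
as the four enriched GO terms.

Library use mirrors the scripts:

```python
import fruitset_wcna as fw

ds  = fw.generate(fw.default_study_spec(seed=1))
res = fw.analyze_pair(ds.matrices["transcript"], ds.matrices["metabolite"],
                      ds.design, ds.annotation, ("iaa9", "MTJi"), fw.RunConfig())
print(res.partition.n_modules_min_size(5), round(res.partition.q, 3))
```

There is also a `fruitset-wcna` CLI with `simulate`, `preprocess`,
`network`, `enrich`, `pca`, `diff`, `run` and `validate` subcommands; a
single `run --config cfg.yaml --seed N --out dir` executes the whole
pipeline and records every resolved default in `provenance.json`.

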