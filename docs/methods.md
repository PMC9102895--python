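# Methods

## The analysis model

The pipeline treats a multi-omics fruit-set experiment as a
genotype × stage × treatment factorial design with replicate
measurements of three feature layers (transcripts, metabolites,
hormones). Its object of inference is the *co-abundance structure* of
the most variable transcripts and metabolites within one mutant /
wild-type genotype pair: which features move together across the design
cells, which communities ("modules") they form, which nodes are most
connected ("hubs"), and which functional categories the modules are
enriched for. A second, orthogonal question — which hormones differ
between mutant and wild type at which stage — is answered by per-stratum
two-sample testing with FDR tiers.

### Preprocessing

Abundances are log₂(v + offset)-transformed (offset 1.0 by default;
values are linear-scale intensities or pmol/g FW concentrations, so the
offset only matters near zero). Replicates are averaged per occupied
(genotype, stage, treatment) cell; a cell with at least one observed
replicate gets the mean of the observed values, an all-non-detect cell
stays missing. Variability is scored per feature as the mean absolute
deviation about the mean, MAD(x) = mean|xᵢ − x̄|, over non-missing
entries; features with < 2 observations or > 50 % missing are excluded
(both thresholds configurable, and a median/median robust variant is
available). Because transcript and metabolite intensities live on
different scales, each feature's MAD is divided by its layer's median
MAD before the joint ranking (`layer_scale`); this keeps scores
non-negative and makes "top 600 across both layers" meaningful. The
selected features are z-scored per feature (ddof = 1). Ranking on
replicate-averaged cell profiles (rather than replicate columns) is the
default; z-scoring does not alter subsequent correlations.

### Network and modules

Pearson correlation (Spearman selectable) over pairwise-complete cell
columns defines an unsigned network: edge (i, j) iff |r| ≥ τ, weight
|r|. τ defaults to 0.8 — a hard threshold chosen so that the planted
within-module correlation (0.9) survives and background correlation
does not; it is surfaced prominently in config and provenance because
results are sensitive to it. Isolated nodes are retained so module
tables account for every selected feature. An edgeless network is an
error directing the caller to lower τ, not a silent Q = 0.

Modules come from a from-scratch agglomerative fast-greedy
(Clauset–Newman–Moore) optimiser of Newman–Girvan modularity
Q = Σ_c (e_cc − a_c²), where e_cc is the fraction of edges inside
community c and a_c its fraction of edge endpoints. Starting from
singletons, the connected pair of communities with maximal
ΔQ = w_ij/m − 2 a_i a_j is merged; the dendrogram is cut at the maximum
Q encountered (the earliest such cut on exact ties). Determinism and
order-invariance are guaranteed by two choices: ties in ΔQ are broken
by the lexicographically smallest pair of community representatives
(a community's representative is its smallest node id), and for the
default unweighted Q all comparisons are carried out in integer
arithmetic on the common denominator 4m² (ΔQ·4m² = 4m·w_ij −
2·deg_i·deg_j), so mathematically equal gains are *exactly* equal. A
weighted-modularity variant (|r| weights, float arithmetic) is
selectable. Module labels M1…Mk are assigned by descending size, then
smallest member id. Hubs are ranked by incident edge count — the same
statistic used to report the most connected genes of a module — with
ascending node id as tie-break.

### Enrichment

Per (module, GO term): k = annotated module members carrying the term,
n = annotated module size, K = universe carriers, N = universe size;
p = P(X ≥ k), X ~ Hypergeometric(N, K, n) (scipy's survival function,
computed stably in log space). The universe is the annotated portion of
the analysed feature set — the platform universe, not the whole genome —
guarding against platform bias; terms with K < 3 are skipped. BH
adjustment is pooled over all (module, term) tests of one network;
significance is q < 0.05. No GO-graph propagation or elim/weight-style
topology correction is applied; the annotation is taken as given.

### Ordination and differential tiers

PCA is the SVD of the centred (and by default unit-scaled, since
transcript and metabolite rows have heterogeneous scales) sample ×
feature matrix; missing values are imputed by feature mean first
(logged). The sign convention — largest-magnitude loading of each
component positive — makes outputs reproducible. Differential testing
is Welch's t per feature within each (stage, treatment) stratum,
mutant vs wild type (or any two levels of any design factor);
zero-variance degenerate groups are handled explicitly (identical
groups → p = 1). p-values are pooled across all testable (feature,
stratum) rows of a contrast for BH; tiers: `**` q < 0.005, `*`
0.005 ≤ q < 0.05, else ns. Strata with < 2 observed replicates in
either group are reported `untestable` rather than dropped. The choice
of a per-stratum pairwise test (rather than ANOVA over stages, which is
available via config) matches how stage-wise significance stars are
conventionally reported for hormone time courses; the BH family scope
(within contrast, across features and strata) is a documented choice —
nothing in the analysis depends on it being the only defensible one.

### Cross-network comparison

Networks from different genotype pairs are built from different samples,
so "the same module" can only be recognised through shared biology.
Three intersections are reported: common nodes (features in every
network), common hubs (in every network's top-20 by degree), and common
modules operationalised as GO terms significant in at least one module
of *every* network. Module-membership overlap between any two partitions
is quantified by Jaccard index. No module-preservation statistic is
computed; the comparison is descriptive.

## The synthetic-data generator

The generator is the test bed: it emits data whose module, hub and
differential structure is known exactly.

* **Design.** Genotype pairs × stages (−2, 0, 2, 4, 8 DAF) × treatments.
  Stages ≤ 0 are pre-flowering and carry no treatment arm; declared
  missing cells (a male-sterile line's pollinated arm, stages sampled
  only for one pair) are simply absent, not NA columns. Replicates per
  layer default to 3 (transcripts, hormones) and 5 (metabolites).
* **Blocks.** Each planted block owns a latent profile: a smooth random
  walk over stages within each (genotype, treatment) arm, standardised
  and then orthogonalised (modified Gram–Schmidt) against the other
  latents so planted modules are mutually uncorrelated by construction.
  A member feature is λ·latent + ε with ε ~ N(0, σ²) per sample and λ
  chosen so corr(feature, latent) = √r, giving expected pairwise
  within-block correlation r (default 0.9) at replicate level.
* **Hubs.** A hub feature tracks its own latent almost perfectly
  (ρ = 0.99). Satellites mix the hub latent with a satellite-specific
  *cell-level* component: the specific component, unlike measurement
  noise, does not shrink when replicates are averaged, so the
  hub–satellite correlation lands at its target (default 0.85) on the
  replicate-averaged profiles the network stage actually correlates.
  Two satellites share only the hub latent, so their mutual correlation
  is ≈ target², and the default obeys the identifiability rule
  target² < τ < target: the planted object is a star, not a clique.
  (With a single shared latent and a 0.9 target — the naive
  construction — satellites form a near-clique above τ and the "hub" is
  not identifiable by degree at all.)
* **Differential effects.** Mean shifts in units of the layer noise SD,
  applied to samples of matching design cells. The default study plants
  a ~100-fold (ln 100 on the log scale) auxin + gibberellin spike in
  pollinated `iaa9` samples at 2–4 DAF, giving IAA cell means near
  3 × 10³ pmol/g FW from a 30 pmol/g baseline.
* **Scales and non-detects.** Transcripts/metabolites are emitted as
  2^(log-signal) positive intensities (baselines N(8, 1.5) and
  N(15, 2) log₂ units); hormones as exp(log-signal) pmol/g FW with
  log-noise SD 0.3 (≈ 35 % CV, typical of targeted hormone
  quantification) and a 0.5 pmol/g detection limit below which values
  become non-detects (`ND`).
* **Annotation.** Each planted transcript block carries a
  characteristic GO term covering ~90 % of its members plus a ~0.5 %
  background rate, among a pool of background terms.

What the generator does *not* emulate: raw microarray/MS signal
processing, count noise for RNA-seq, correlated measurement batches,
heavy-tailed abundance distributions, or annotation incompleteness
beyond uniform coverage. Passing recovery tests therefore demonstrates
that the pipeline's inference machinery is correct under its own model
assumptions — not that real fruit-set data would yield modules this
clean; real within-module correlations are weaker and real τ/K choices
materially affect module boundaries.

## Numerical and design choices

* Canonical output: all writers emit fixed 10-significant-digit floats,
  canonical row order and `ND` for missing, so identical runs are
  byte-identical (verified end-to-end).
* Exact greedy arithmetic (integer ΔQ, see above) makes module detection
  invariant to feature order; the merge history and Q are recomputed
  independently after the run as an internal consistency check
  (tolerance 1e-9, stored Q then set to the recount).
* Zero-variance features cannot be z-scored (error naming the feature
  during joint assembly) and are dropped with a warning from
  correlation input.
* Problem sizes in tests and the acceptance script (e.g. 130-feature
  recovery designs, 20–200 seed batches, a 700-transcript pipeline
  smoke matrix, 10 000 transcripts in the full acceptance run) are
  chosen as the smallest sizes at which the measured statistics are
  stable.
* Statistical power at the study's replicate counts is intrinsically
  limited: with n = 3 per group, Welch's t has ~4 degrees of freedom,
  so even a 5-SD shift rarely survives BH across 100 features at the
  q < 0.005 tier (measured ≈ 0–2 % of seeds). Per-feature calibration
  is verified instead at n = 5 without a multiplicity burden (≥ 95 %
  detection of a 3-SD shift). Any stage-wise tier reported at such
  sample sizes reflects either a very large effect or a very small
  family; the tier table should be read accordingly.

## Known limitations

* Hard-threshold unsigned networks, not soft-threshold/topological-
  overlap WGCNA; the two agree only when the correlation structure is
  strongly block-like.
* The fast-greedy optimiser has the usual resolution limit of
  modularity maximisation (small modules merge into large ones near the
  limit m^½).
* The comparison stage is descriptive; it attaches no significance to
  cross-network overlaps.
* GO enrichment ignores the term hierarchy; a parent and child term can
  both be reported.
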