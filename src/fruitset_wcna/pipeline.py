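"""End-to-end orchestration: simulate -> preprocess -> network -> modules
-> hubs -> enrichment -> PCA -> differential testing -> cross-network
comparison, with every default recorded in a provenance file.

A run is deterministic: the same config and seed produce byte-identical
artifacts.  Each mutant / wild-type genotype pair yields its own joint
matrix and network; hormones are tested mutant-vs-wild-type per stage and
treatment; the comparison stage intersects the pair-level results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import compare as cmp
from . import io as fio
from . import synthetic
from .enrichment import module_enrichment
from .network import build_network, correlation_matrix, fast_greedy_modules, hub_ranking
from .preprocess import assemble_joint, cell_means, log_transform, mad_scores, select_top_k
from .stats import differential_test, pca

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of a run.  Paper-style constants are the defaults: top
    k=600 joint features, unsigned network, FDR tiers 0.05 / 0.005."""

    out_dir: str = "results/run"
    seed: int = 0
    # inputs: either synthetic (generated) or paths to matrices
    synthetic: bool = True
    n_transcripts: int = 10000
    n_metabolites: int = 715
    transcript_path: str | None = None
    metabolite_path: str | None = None
    hormone_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    genotype_pairs: tuple = ()          # resolved from the synthetic spec when empty
    # preprocessing
    k: int = 600
    log_offset: float = 1.0
    mad_statistic: str = "mean"
    mad_layer_scale: bool = True
    correlate_on: str = "cell_means"    # or "replicates"
    # network
    tau: float = 0.8
    correlation_kind: str = "pearson"
    weighted_modularity: bool = False
    # statistics
    fdr_star: float = 0.05
    fdr_double_star: float = 0.005
    test_family: str = "welch"
    min_term_size: int = 3
    top_h: int = 20

    def validate(self) -> list[str]:
        """Resolved-defaults report; raises on invalid values."""
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must be in (0, 1]")
        for name in ("fdr_star", "fdr_double_star"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")
        return [f"{key} = {value!r}" for key, value in sorted(asdict(self).items())]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "genotype_pairs" in raw:
            raw["genotype_pairs"] = tuple(tuple(p) for p in raw["genotype_pairs"])
        return cls(**raw)


@dataclass
class PairResult:
    pair: tuple
    joint: object
    network: object
    partition: object
    hubs: pd.DataFrame
    enrichment: pd.DataFrame
    ranking: object = None


def analyze_pair(transcripts, metabolites, design, annotation, pair, cfg: RunConfig) -> PairResult:
    """The per-genotype-pair analysis: subset samples, log-transform,
    average replicates, select the top-k most variable transcript +
    metabolite features, build the unsigned correlation network and
    partition it, rank hubs, test GO enrichment."""
    samples = design.samples_for(genotypes=pair)
    if not samples:
        raise ValueError(f"no samples found for genotypes {pair}")
    d = design.subset([s for s in samples])
    m_t = transcripts.subset_samples([s for s in transcripts.sample_ids if s in set(samples)])
    m_m = metabolites.subset_samples([s for s in metabolites.sample_ids if s in set(samples)])

    m_t = log_transform(m_t, cfg.log_offset)
    m_m = log_transform(m_m, cfg.log_offset)
    ct = cell_means(m_t, d)
    cm = cell_means(m_m, d)
    if cfg.correlate_on == "replicates":
        # rank/correlate on replicate-level columns; align metabolite columns
        # to the transcript sample set is not possible (different replicate
        # counts), so replicate-level mode still averages metabolites
        ct_rank, cm_rank = m_t, cm
    else:
        ct_rank, cm_rank = ct, cm
    both = pd.concat([ct_rank.values, cm_rank.values])
    meta = pd.concat([ct_rank.feature_meta, cm_rank.feature_meta])
    ranking = mad_scores(fio.OmicsMatrix(both, meta), statistic=cfg.mad_statistic,
                         layer_scale=cfg.mad_layer_scale)
    selected = select_top_k(ranking, cfg.k, layers={"transcript", "metabolite"})
    joint = assemble_joint(ct, cm, selected, ranking=ranking, k=cfg.k)

    r = correlation_matrix(joint, kind=cfg.correlation_kind)
    net = build_network(r, tau=cfg.tau, layers=joint.layers, correlation_kind=cfg.correlation_kind)
    partition = fast_greedy_modules(net, weighted=cfg.weighted_modularity)
    hubs = hub_ranking(net, partition)
    enr = module_enrichment(partition, annotation, min_term_size=cfg.min_term_size)
    return PairResult(tuple(pair), joint, net, partition, hubs, enr, ranking)


def run(cfg: RunConfig) -> Path:
    """Execute the full pipeline and write every artifact under
    ``cfg.out_dir``.  Returns the run directory."""
    resolved = cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    provenance: dict = {"config": dict(sorted(asdict(cfg).items())), "stages": {}}

    def stage(name):
        log.info("stage %-12s (t=%.1fs)", name, time.time() - t0)
        return name

    # -- inputs ------------------------------------------------------------
    name = stage("inputs")
    try:
        if cfg.synthetic:
            spec = synthetic.default_study_spec(seed=cfg.seed,
                                                n_transcripts=cfg.n_transcripts,
                                                n_metabolites=cfg.n_metabolites)
            ds = synthetic.generate(spec)
            transcripts, metabolites = ds.matrices["transcript"], ds.matrices["metabolite"]
            hormones, design, annotation = ds.matrices["hormone"], ds.design, ds.annotation
            pairs = list(spec.genotype_pairs)
            data_dir = out / "data"
            for layer, m in ds.matrices.items():
                fio.write_matrix(m, data_dir / f"{layer}s.tsv")
            fio.write_design(design, data_dir / "design.tsv")
            fio.write_annotation(annotation, data_dir / "annotation.tsv")
        else:
            transcripts = fio.read_matrix(cfg.transcript_path, layer="transcript")
            metabolites = fio.read_matrix(cfg.metabolite_path, layer="metabolite")
            hormones = fio.read_matrix(cfg.hormone_path, layer="hormone") if cfg.hormone_path else None
            design = fio.read_design(cfg.design_path)
            annotation = fio.read_annotation(cfg.annotation_path)
            pairs = [tuple(p) for p in cfg.genotype_pairs]
            if not pairs:
                raise ValueError("genotype_pairs must be given for file inputs")
        for m in (transcripts, metabolites, hormones):
            if m is None:
                continue
            orphan = [s for s in m.sample_ids if s not in design.table.index]
            if orphan:
                raise ValueError(f"matrix samples missing from design: {orphan[:5]}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc

    # -- per-pair network analysis ----------------------------------------
    pair_results: dict[str, PairResult] = {}
    for pair in pairs:
        name = stage(f"network[{pair[0]}]")
        try:
            res = analyze_pair(transcripts, metabolites, design, annotation, pair, cfg)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        pid = pair[0]
        pair_results[pid] = res
        pdir = out / f"pair_{pid}"
        fio.write_matrix(fio.OmicsMatrix(res.joint.values, pd.DataFrame({"layer": res.joint.layers})),
                         pdir / "joint.tsv")
        fio.write_edgelist(res.network.graph, pdir / "network_edges.tsv")
        g = res.network.graph.copy()
        for n in g.nodes:
            g.nodes[n]["module"] = res.partition.assignment[n]
            g.nodes[n]["degree"] = int(g.degree(n))
        fio.write_graphml(g, pdir / "network.graphml")
        modules = pd.DataFrame(
            [(n, res.partition.assignment[n]) for n in sorted(res.partition.assignment, key=str)],
            columns=["node", "module"])
        fio.write_table(modules, pdir / "modules.tsv")
        fio.write_table(res.hubs, pdir / "hubs.tsv")
        fio.write_table(res.enrichment, pdir / "enrichment.tsv")
        provenance["stages"][name] = {
            "n_selected": int(res.joint.values.shape[0]),
            "n_edges": res.network.n_edges,
            "n_modules": res.partition.n_modules,
            "n_modules_min5": res.partition.n_modules_min_size(5),
            "modularity_Q": round(res.partition.q, 10),
        }

    # -- ordination --------------------------------------------------------
    name = stage("pca")
    try:
        first = pair_results[pairs[0][0]]
        pc = pca(first.joint.values, center=True, unit_scale=True)
        fio.write_table(pc.scores.reset_index(names="sample"), out / "pca_scores.tsv")
        fio.write_table(pc.loadings.reset_index(names="feature"), out / "pca_loadings.tsv")
        provenance["stages"][name] = {
            "explained_variance_fraction": [round(float(f), 10) for f in pc.explained_variance_fraction[:5]],
        }
    except Exception as exc:
        raise PipelineError(name, exc) from exc

    # -- hormone differential testing -------------------------------------
    name = stage("differential")
    try:
        diff_tables = []
        if hormones is not None:
            h_log = log_transform(hormones, cfg.log_offset)
            for mut, wt in pairs:
                ids = design.samples_for(genotypes=(mut, wt))
                sub = h_log.subset_samples([s for s in h_log.sample_ids if s in set(ids)])
                diff_tables.append(differential_test(sub, design, "genotype", mut, wt))
            diff = pd.concat(diff_tables, ignore_index=True)
            fio.write_table(diff, out / "differential_hormones.tsv")
            provenance["stages"][name] = {
                "n_tests": int(diff["p"].notna().sum()),
                "n_significant": int(diff["tier"].isin(["*", "**"]).sum()),
            }
    except Exception as exc:
        raise PipelineError(name, exc) from exc

    # -- cross-network comparison ------------------------------------------
    name = stage("compare")
    try:
        if len(pair_results) >= 2:
            ids = list(pair_results)
            summary = cmp.summarize(
                ids,
                {i: pair_results[i].network for i in ids},
                {i: pair_results[i].partition for i in ids},
                {i: pair_results[i].enrichment for i in ids},
                {i: pair_results[i].hubs for i in ids},
                top_h=cfg.top_h,
            )
            rows = ([("common_node", n) for n in sorted(summary.common_nodes)]
                    + [("common_term", t) for t in sorted(summary.common_terms)]
                    + [("common_hub", h) for h in sorted(summary.common_hubs)])
            fio.write_table(pd.DataFrame(rows, columns=["kind", "feature"]), out / "compare_summary.tsv")
            provenance["stages"][name] = {
                "n_common_nodes": len(summary.common_nodes),
                "n_common_terms": len(summary.common_terms),
                "n_common_hubs": len(summary.common_hubs),
            }
    except Exception as exc:
        raise PipelineError(name, exc) from exc

    provenance["resolved_defaults"] = resolved
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run complete in %.1fs -> %s", time.time() - t0, out)
    return out
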