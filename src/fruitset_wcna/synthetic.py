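"""Synthetic multi-omics fruit-set datasets with known planted structure.

The generator emulates the design of a tomato fruit-set experiment:
parthenocarpic mutant / wild-type genotype pairs sampled at stages around
flowering (days after flowering, DAF), with pollinated (P) and emasculated
(E) treatment arms after flowering and untreated pistils before, and three
omics layers measured on the same material — transcripts (microarray-like
intensities), metabolites (MS intensities) and hormones (pmol/g fresh
weight).

Planted structure gives every downstream stage a ground truth:

* **blocks** — sets of features driven by a shared latent profile, so that
  the expected pairwise correlation within a block hits a requested target
  (these are what module detection should recover);
* **hubs** — a single feature strongly coupled to a swarm of satellite
  features (what degree ranking should put on top);
* **differential effects** — mean shifts, in units of the noise SD, applied
  to the samples of selected design cells (what the differential tier test
  should flag).

Generative model: each block or hub owns a latent profile built as a smooth
random walk over stages within every (genotype, treatment) arm,
standardised and then orthogonalised against the other latents so planted
modules are mutually uncorrelated by construction.  A member feature with
within-block correlation target ``r`` is ``lambda * latent + noise`` with
``lambda`` chosen so that corr(feature, latent) = sqrt(r), which makes the
expected correlation between two members equal ``r``.  Unplanted features
are pure noise.  Transcript and metabolite layers are emitted as positive
linear-scale intensities (2**log-signal); hormones as exp(log-signal)
concentrations with values below a detection limit reported as non-detects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GoAnnotation, OmicsMatrix, SampleDesign

# corr(hub feature, its latent); satellites are scaled so that
# corr(hub, satellite) equals the requested hub correlation
RHO_HUB = 0.99


class SpecError(ValueError):
    """Invalid synthetic specification."""


@dataclass(frozen=True)
class PlantedBlock:
    block_id: str
    members: tuple[str, ...]
    correlation: float = 0.9
    go_term: tuple[str, str] | None = None  # (term id, term name), transcripts only
    go_coverage: float = 0.9


@dataclass(frozen=True)
class PlantedHub:
    """A star: one feature coupled to ``n_satellites`` features.

    ``correlation`` is the target hub-satellite correlation measured on
    replicate-averaged profiles.  Two satellites share only the hub's
    latent, so their mutual correlation is ~``correlation**2``; keep
    ``correlation**2`` below the network edge threshold tau (and
    ``correlation`` above it) or the star degenerates into a clique in
    which the hub is not distinguishable by degree."""

    hub_id: str
    n_satellites: int
    correlation: float = 0.85  # target corr(hub, satellite)


@dataclass(frozen=True)
class DifferentialEffect:
    feature_id: str
    genotype: str | None = None
    treatment: str | None = None
    stages: tuple[int, ...] | None = None
    effect_sd: float = 3.0

    def matches(self, genotype: str, stage: int, treatment: str) -> bool:
        if self.genotype is not None and genotype != self.genotype:
            return False
        if self.treatment is not None and treatment != self.treatment:
            return False
        if self.stages is not None and stage not in self.stages:
            return False
        return True


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a planted multi-omics dataset."""

    n_transcripts: int = 10000
    n_metabolites: int = 715
    n_hormones: int = 42
    genotype_pairs: tuple[tuple[str, str], ...] = ()
    stages: tuple[int, ...] = (-2, 0, 2, 4)
    treatments: tuple[str, ...] = ("P", "E")
    replicates: dict = field(default_factory=lambda: {"transcript": 3, "metabolite": 5, "hormone": 3})
    planted_blocks: tuple[PlantedBlock, ...] = ()
    planted_hubs: tuple[PlantedHub, ...] = ()
    differential_effects: tuple[DifferentialEffect, ...] = ()
    missing_cells: tuple[dict, ...] = ()  # each {genotype?, stage?, treatment?}
    noise_sd: float = 1.0
    noise_sd_by_layer: dict = field(default_factory=dict)
    hormone_detection_limit: float = 0.5  # pmol/g FW; below -> non-detect
    n_background_terms: int = 30
    seed: int = 0

    # ------------------------------------------------------------------
    def feature_ids(self, layer: str) -> list[str]:
        if layer == "transcript":
            return [f"T{i:05d}" for i in range(1, self.n_transcripts + 1)]
        if layer == "metabolite":
            return [f"M{i:04d}" for i in range(1, self.n_metabolites + 1)]
        if layer == "hormone":
            base = ["IAA", "GA1", "GA4", "GA20", "tZ", "ABA", "SA", "JA"]
            extra = [f"H{i:02d}" for i in range(1, max(0, self.n_hormones - len(base)) + 1)]
            return (base + extra)[: self.n_hormones]
        raise ValueError(f"unknown layer {layer!r}")

    def layer_noise_sd(self, layer: str) -> float:
        return float(self.noise_sd_by_layer.get(layer, self.noise_sd))

    def genotypes(self) -> list[str]:
        out: list[str] = []
        for mut, wt in self.genotype_pairs:
            out.extend([mut, wt])
        return out

    def cell_missing(self, genotype: str, stage: int, treatment: str) -> bool:
        for cell in self.missing_cells:
            if "genotype" in cell and cell["genotype"] != genotype:
                continue
            if "stage" in cell and int(cell["stage"]) != stage:
                continue
            if "treatment" in cell and cell["treatment"] != treatment:
                continue
            return True
        return False

    def design_cells(self) -> list[tuple[str, int, str]]:
        """Occupied (genotype, stage, treatment) cells, canonical order.
        Pre-flowering stages (DAF <= 0) carry no pollination treatment."""
        cells = []
        for genotype in self.genotypes():
            for stage in sorted(self.stages):
                arms = ("none",) if stage <= 0 else tuple(self.treatments)
                for trt in arms:
                    if not self.cell_missing(genotype, stage, trt):
                        cells.append((genotype, stage, trt))
        return cells

    def validate(self) -> None:
        if self.n_transcripts <= 0 or self.n_metabolites < 0 or self.n_hormones < 0:
            raise SpecError("feature counts must be positive")
        if not self.genotype_pairs:
            raise SpecError("at least one genotype pair required")
        if self.noise_sd <= 0 or any(v <= 0 for v in self.noise_sd_by_layer.values()):
            raise SpecError("noise_sd must be positive")
        all_features = set()
        for layer in ("transcript", "metabolite", "hormone"):
            all_features.update(self.feature_ids(layer))
        seen: set[str] = set()
        for blk in self.planted_blocks:
            members = set(blk.members)
            if members & seen:
                raise SpecError(f"block {blk.block_id}: overlapping membership {sorted(members & seen)[:3]}")
            unknown = members - all_features
            if unknown:
                raise SpecError(f"block {blk.block_id}: unknown feature ids {sorted(unknown)[:3]}")
            if not (0.0 < blk.correlation <= 1.0):
                raise SpecError(f"block {blk.block_id}: correlation target must be in (0, 1]")
            seen |= members
        for hub in self.planted_hubs:
            if hub.hub_id not in all_features:
                raise SpecError(f"hub {hub.hub_id}: unknown feature id")
            if hub.hub_id in seen:
                raise SpecError(f"hub {hub.hub_id}: already a block member")
            if not (0.0 < hub.correlation <= RHO_HUB):
                raise SpecError(f"hub {hub.hub_id}: correlation must be in (0, {RHO_HUB}]")
            seen.add(hub.hub_id)
        for eff in self.differential_effects:
            if eff.feature_id not in all_features:
                raise SpecError(f"differential effect on unknown feature {eff.feature_id}")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    matrices: dict  # layer -> OmicsMatrix
    design: SampleDesign
    annotation: GoAnnotation
    latents: pd.DataFrame            # cells x latent profiles (block/hub ids)
    block_of: dict                   # feature id -> block id (hubs: hub id; satellites too)
    hub_satellites: dict             # hub id -> tuple of satellite feature ids


def _layer_of_feature(spec: SyntheticSpec, fid: str) -> str:
    for layer in ("transcript", "metabolite", "hormone"):
        if fid in set(spec.feature_ids(layer)):
            return layer
    raise KeyError(fid)


def _latent_profiles(spec: SyntheticSpec, cells, rng: np.random.Generator) -> pd.DataFrame:
    """One standardized latent per planted block and hub: smooth random walk
    over stages within each (genotype, treatment) arm, then orthogonalised
    across latents (modified Gram-Schmidt) so planted modules are mutually
    uncorrelated by construction."""
    names = [b.block_id for b in spec.planted_blocks] + [h.hub_id for h in spec.planted_hubs]
    n_cells = len(cells)
    cols = {}
    # group cell indices by (genotype, treatment), stage-ordered (cells are canonical)
    arms: dict[tuple[str, str], list[int]] = {}
    for i, (g, s, t) in enumerate(cells):
        arms.setdefault((g, t), []).append(i)
    raw = np.empty((n_cells, len(names)))
    for j, _name in enumerate(names):
        v = np.empty(n_cells)
        for idx in arms.values():
            walk = np.cumsum(rng.normal(0.0, 1.0, size=len(idx)))
            v[np.asarray(idx)] = walk + rng.normal(0.0, 1.0)
        raw[:, j] = v
    # standardise, then orthogonalise sequentially when there is room
    for j in range(len(names)):
        col = raw[:, j] - raw[:, j].mean()
        if len(names) < n_cells:
            for k in range(j):
                prev = raw[:, k]
                col = col - (col @ prev) / (prev @ prev) * prev
            col = col - col.mean()
        sd = col.std()
        if sd < 1e-9:  # degenerate draw; fall back to white noise
            col = rng.normal(0.0, 1.0, size=n_cells)
            col = col - col.mean()
            sd = col.std()
        raw[:, j] = col / sd
    for j, name in enumerate(names):
        cols[name] = raw[:, j]
    index = [f"{g}_{s}_{t}" for g, s, t in cells]
    return pd.DataFrame(cols, index=index)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full dataset from a spec.  Pure function of the spec:
    identical specs (including seed) give identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cells = spec.design_cells()
    latents = _latent_profiles(spec, cells, rng)

    # resolve hub satellites: first unassigned features of the hub's layer
    assigned = set()
    for blk in spec.planted_blocks:
        assigned |= set(blk.members)
    assigned |= {h.hub_id for h in spec.planted_hubs}
    hub_satellites: dict[str, tuple[str, ...]] = {}
    for hub in spec.planted_hubs:
        layer = _layer_of_feature(spec, hub.hub_id)
        free = [f for f in spec.feature_ids(layer) if f not in assigned]
        if len(free) < hub.n_satellites:
            raise SpecError(f"hub {hub.hub_id}: not enough unassigned {layer} features for satellites")
        sats = tuple(free[: hub.n_satellites])
        hub_satellites[hub.hub_id] = sats
        assigned |= set(sats)

    block_of: dict[str, str] = {}
    for blk in spec.planted_blocks:
        for fid in blk.members:
            block_of[fid] = blk.block_id
    for hub in spec.planted_hubs:
        block_of[hub.hub_id] = hub.hub_id
        for fid in hub_satellites[hub.hub_id]:
            block_of[fid] = hub.hub_id

    # per-feature latent coupling rho = corr(feature, latent)
    rho: dict[str, tuple[str, float]] = {}
    for blk in spec.planted_blocks:
        r = math.sqrt(blk.correlation)
        for fid in blk.members:
            rho[fid] = (blk.block_id, r)
    for hub in spec.planted_hubs:
        rho[hub.hub_id] = (hub.hub_id, RHO_HUB)
    # satellites: hub latent + a satellite-specific cell-level component,
    # calibrated so the hub-satellite correlation survives replicate
    # averaging at the target while satellites stay mutually de-correlated
    satellite_coupling: dict[str, tuple[str, float]] = {}
    for hub in spec.planted_hubs:
        for fid in hub_satellites[hub.hub_id]:
            satellite_coupling[fid] = (hub.hub_id, hub.correlation / RHO_HUB)

    effects_by_feature: dict[str, list[DifferentialEffect]] = {}
    for eff in spec.differential_effects:
        effects_by_feature.setdefault(eff.feature_id, []).append(eff)

    matrices: dict[str, OmicsMatrix] = {}
    design_rows = []
    for layer in ("transcript", "metabolite", "hormone"):
        fids = spec.feature_ids(layer)
        if not fids:
            continue
        n_rep = int(spec.replicates.get(layer, 3))
        sigma = spec.layer_noise_sd(layer)
        sample_ids, sample_cells = [], []
        for (g, s, t) in cells:
            for rep in range(1, n_rep + 1):
                sample_ids.append(f"{g}_{s}_{t}_{rep}")
                sample_cells.append((g, s, t))
        n_s = len(sample_ids)
        # log-scale baselines per feature
        if layer == "hormone":
            baseline = np.where(np.isin(fids, ["IAA", "GA1", "GA4", "GA20"]),
                                math.log(30.0),
                                rng.normal(math.log(30.0), 1.5, size=len(fids)))
        elif layer == "transcript":
            baseline = rng.normal(8.0, 1.5, size=len(fids))
        else:
            baseline = rng.normal(15.0, 2.0, size=len(fids))
        cell_idx = np.array([latents.index.get_loc(f"{g}_{s}_{t}") for g, s, t in sample_cells])
        n_cells_total = latents.shape[0]
        values = np.empty((len(fids), n_s))
        for i, fid in enumerate(fids):
            g_log = np.full(n_s, baseline[i])
            if fid in rho:
                latent_name, r = rho[fid]
                lam = sigma * r / math.sqrt(1.0 - r * r) if r < 1.0 else 1e6
                g_log = g_log + lam * latents[latent_name].to_numpy()[cell_idx]
            elif fid in satellite_coupling:
                latent_name, u = satellite_coupling[fid]
                s_tot = 4.0 * sigma  # latent-part SD; dwarfs replicate noise
                own = rng.normal(0.0, 1.0, size=n_cells_total)
                own = (own - own.mean()) / own.std()
                cell_part = (u * latents[latent_name].to_numpy()
                             + math.sqrt(max(0.0, 1.0 - u * u)) * own)
                g_log = g_log + s_tot * cell_part[cell_idx]
            g_log = g_log + rng.normal(0.0, sigma, size=n_s)
            for eff in effects_by_feature.get(fid, ()):  # mean shifts in SD units
                mask = np.array([eff.matches(g, s, t) for g, s, t in sample_cells])
                g_log = g_log + mask * (eff.effect_sd * sigma)
            values[i] = g_log
        if layer == "hormone":
            linear = np.exp(values)
            linear[linear < spec.hormone_detection_limit] = np.nan  # non-detect
        else:
            linear = np.exp2(values)
        df = pd.DataFrame(linear, index=fids, columns=sample_ids)
        meta = pd.DataFrame({"layer": layer}, index=df.index)
        matrices[layer] = OmicsMatrix(df, meta)
        for sid, (g, s, t) in zip(sample_ids, sample_cells):
            design_rows.append((sid, g, s, t, int(sid.rsplit("_", 1)[1])))

    design_df = (pd.DataFrame(design_rows, columns=["sample_id", "genotype", "stage", "treatment", "replicate"])
                 .drop_duplicates("sample_id").set_index("sample_id"))
    design = SampleDesign(design_df)
    annotation = _annotate(spec, rng)
    return SyntheticDataset(spec, matrices, design, annotation, latents, block_of, hub_satellites)


def _annotate(spec: SyntheticSpec, rng: np.random.Generator) -> GoAnnotation:
    """Transcript GO annotation: each block's characteristic term covers
    ``go_coverage`` of its members plus a small background rate, and a pool
    of background terms is scattered uniformly."""
    transcripts = spec.feature_ids("transcript")
    tset = set(transcripts)
    feature_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for blk in spec.planted_blocks:
        if blk.go_term is None:
            continue
        term_id, term_name = blk.go_term
        term_names[term_id] = term_name
        members = [m for m in blk.members if m in tset]
        for fid in members:
            if rng.random() < blk.go_coverage:
                feature_terms.setdefault(fid, set()).add(term_id)
        # background carriers outside the block, ~0.5% of transcripts
        n_bg = max(1, int(0.005 * len(transcripts)))
        for fid in rng.choice(transcripts, size=n_bg, replace=False):
            feature_terms.setdefault(str(fid), set()).add(term_id)
    for b in range(1, spec.n_background_terms + 1):
        term_id = f"GO:BG{b:04d}"
        term_names[term_id] = f"background process {b}"
        n_carry = int(rng.integers(max(3, len(transcripts) // 100), max(4, len(transcripts) // 20)))
        for fid in rng.choice(transcripts, size=min(n_carry, len(transcripts)), replace=False):
            feature_terms.setdefault(str(fid), set()).add(term_id)
    return GoAnnotation(feature_terms, term_names)


def truth_partition(dataset: SyntheticDataset, selected=None) -> dict[str, str]:
    """Planted block assignment (feature id -> block id), with every
    unplanted feature labelled ``"noise"``.  When ``selected`` is given the
    mapping is restricted to those features, mirroring what survives a
    feature-selection step."""
    if selected is None:
        features = []
        for layer in ("transcript", "metabolite", "hormone"):
            if layer in dataset.matrices:
                features.extend(dataset.matrices[layer].feature_ids)
    else:
        features = list(selected)
    return {fid: dataset.block_of.get(fid, "noise") for fid in features}


# ---------------------------------------------------------------------------
# the default study design


def default_study_spec(seed: int = 0, n_transcripts: int = 10000, n_metabolites: int = 715) -> SyntheticSpec:
    """The default dataset: three parthenocarpic mutant / wild-type pairs,
    stages -2..8 DAF, P/E arms, with planted photosynthesis-like and
    cell-cycle-like modules, hubs, and a genotype-specific post-flowering
    hormone spike (auxin and bioactive gibberellins, ~100-fold)."""
    pairs = (("iaa9", "MTJi"), ("della", "MTB"), ("tap3", "MTJt"))
    t = [f"T{i:05d}" for i in range(1, n_transcripts + 1)]
    m = [f"M{i:04d}" for i in range(1, n_metabolites + 1)]
    blocks = (
        PlantedBlock("photosynthesis", tuple(t[0:120]), 0.9,
                     go_term=("GO:0015979", "photosynthesis")),
        PlantedBlock("cell_cycle", tuple(t[120:220]), 0.9,
                     go_term=("GO:0007049", "cell cycle")),
        PlantedBlock("cell_wall", tuple(t[220:300]), 0.88,
                     go_term=("GO:0071554", "cell wall organization")),
        PlantedBlock("oxidoreductase", tuple(t[300:360]), 0.88,
                     go_term=("GO:0016491", "oxidoreductase activity")),
        PlantedBlock("protein_kinase", tuple(t[360:410]), 0.85,
                     go_term=("GO:1902911", "protein kinase complex")),
        PlantedBlock("sugar_metabolites", tuple(m[0:40]), 0.9),
        PlantedBlock("amino_acid_metabolites", tuple(m[40:70]), 0.85),
    )
    hubs = (
        PlantedHub("T00500", 40),   # glucose-1-phosphate-adenylyltransferase-like hub
        PlantedHub("T00600", 30),
    )
    ln100 = math.log(100.0)
    effects = tuple(
        DifferentialEffect(h, genotype="iaa9", treatment="P", stages=(2, 4), effect_sd=ln100 / 0.3)
        for h in ("IAA", "GA1", "GA4", "GA20")
    )
    return SyntheticSpec(
        n_transcripts=n_transcripts,
        n_metabolites=n_metabolites,
        n_hormones=42,
        genotype_pairs=pairs,
        stages=(-2, 0, 2, 4, 8),
        treatments=("P", "E"),
        replicates={"transcript": 3, "metabolite": 5, "hormone": 3},
        planted_blocks=blocks,
        planted_hubs=hubs,
        differential_effects=effects,
        # stage 8 sampled only for the tap3 pair; tap3 itself is male-sterile
        # (no pollinated arm)
        missing_cells=(
            {"genotype": "iaa9", "stage": 8}, {"genotype": "MTJi", "stage": 8},
            {"genotype": "della", "stage": 8}, {"genotype": "MTB", "stage": 8},
            {"genotype": "tap3", "treatment": "P"},
        ),
        noise_sd=1.0,
        noise_sd_by_layer={"hormone": 0.3},
        seed=seed,
    )


def small_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A scaled-down single-pair design used in tests and examples."""
    t = [f"T{i:05d}" for i in range(1, 501)]
    m = [f"M{i:04d}" for i in range(1, 101)]
    blocks = (
        PlantedBlock("photosynthesis", tuple(t[0:30]), 0.9, go_term=("GO:0015979", "photosynthesis")),
        PlantedBlock("cell_cycle", tuple(t[30:60]), 0.9, go_term=("GO:0007049", "cell cycle")),
        PlantedBlock("sugar_metabolites", tuple(m[0:15]), 0.9),
    )
    base = SyntheticSpec(
        n_transcripts=500,
        n_metabolites=100,
        n_hormones=10,
        genotype_pairs=(("mut", "wt"),),
        stages=(-2, 0, 2, 4, 8),
        treatments=("P", "E"),
        replicates={"transcript": 3, "metabolite": 3, "hormone": 3},
        planted_blocks=blocks,
        planted_hubs=(PlantedHub("T00400", 20),),
        noise_sd=1.0,
        noise_sd_by_layer={"hormone": 0.3},
        n_background_terms=10,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base
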