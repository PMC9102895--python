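"""Abundance transformation and joint feature selection.

The network stage works on a single matrix holding the most variable
transcripts and metabolites together.  The steps here produce it:
log-transform, replicate averaging per design cell, mean-absolute-deviation
(MAD) ranking, top-K selection across the two layers, and per-feature
standardisation.

MAD here is the *mean* absolute deviation about the mean,
``mean(|x - mean(x)|)``; the median-based robust variant common in WGCNA
practice is available via ``statistic="median"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OmicsMatrix, SampleDesign

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class FeatureRanking:
    """Features ordered by descending variability score; ties broken by
    ascending feature id so the ordering is total and deterministic."""

    scores: pd.Series          # index feature_id, values >= 0, sorted
    layers: pd.Series          # feature_id -> layer
    excluded: tuple[str, ...]  # features dropped (too few observations)
    statistic: str = "mean"

    def __post_init__(self) -> None:
        order = sorted(self.scores.index, key=lambda f: (-self.scores[f], f))
        self.scores = self.scores.loc[order]

    def top(self, k: int, layers=None) -> list[str]:
        return select_top_k(self, k, layers)


@dataclass
class JointMatrix:
    """Selected transcript+metabolite features, per-feature z-scored
    (mean 0, SD 1 with ddof=1 across columns)."""

    values: pd.DataFrame       # features x cells, standardized
    layers: pd.Series          # feature_id -> layer
    ranking: FeatureRanking | None
    k: int | None


def log_transform(m: OmicsMatrix, offset: float = 1.0) -> OmicsMatrix:
    """v -> log2(v + offset); non-detects stay missing."""
    if offset <= 0:
        raise PreprocessError("offset must be positive")
    arr = m.values.to_numpy(dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and finite.min() < 0:
        raise PreprocessError("negative abundance encountered; log transform undefined")
    out = np.log2(arr + offset)
    return OmicsMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
                       m.feature_meta.copy())


def cell_means(m: OmicsMatrix, d: SampleDesign) -> OmicsMatrix:
    """Average replicates: one column per occupied (genotype, stage,
    treatment) cell; a cell with at least one non-missing replicate gets the
    mean of the observed values, otherwise stays missing."""
    missing = [s for s in m.sample_ids if s not in d.table.index]
    if missing:
        raise PreprocessError(f"samples absent from design: {missing[:5]}")
    cells: dict[str, list[str]] = {}
    for sid in m.sample_ids:
        g, s, t = d.cell_of(sid)
        cells.setdefault(f"{g}_{s}_{t}", []).append(sid)
    order = sorted(cells, key=lambda c: _cell_sort_key(c, d, cells))
    out = pd.DataFrame(index=m.values.index, columns=order, dtype=float)
    for cell in order:
        out[cell] = m.values[cells[cell]].mean(axis=1, skipna=True)
    return OmicsMatrix(out, m.feature_meta.copy())


def _cell_sort_key(cell: str, d: SampleDesign, cells) -> tuple:
    g, s, t = d.cell_of(cells[cell][0])
    return (g, s, t)


def mad_scores(m: OmicsMatrix, statistic: str = "mean",
               max_missing_frac: float = 0.5, layer_scale: bool = False) -> FeatureRanking:
    """Per-feature variability score across columns.

    ``statistic="mean"``: mean(|v - mean(v)|) over non-missing entries;
    ``"median"``: median(|v - median(v)|).  Features with fewer than two
    observations or more than ``max_missing_frac`` missing are excluded
    (and recorded).  With ``layer_scale`` each score is divided by its
    layer's median score, making transcript and metabolite scores
    comparable before a joint ranking.
    """
    if statistic not in ("mean", "median"):
        raise PreprocessError(f"unknown MAD statistic {statistic!r}")
    vals = m.values.to_numpy(dtype=float)
    n_cols = vals.shape[1]
    scores, excluded = {}, []
    for fid, row in zip(m.feature_ids, vals):
        obs = row[np.isfinite(row)]
        if obs.size < 2 or (n_cols - obs.size) / n_cols > max_missing_frac:
            excluded.append(fid)
            continue
        if statistic == "mean":
            scores[fid] = float(np.mean(np.abs(obs - obs.mean())))
        else:
            med = np.median(obs)
            scores[fid] = float(np.median(np.abs(obs - med)))
    ser = pd.Series(scores, dtype=float)
    layers = m.feature_meta.loc[ser.index, "layer"]
    if layer_scale:
        for layer in layers.unique():
            sel = layers == layer
            med = ser[sel].median()
            if med > 0:
                ser[sel] = ser[sel] / med
    if excluded:
        log.info("mad_scores: excluded %d feature(s) with insufficient observations", len(excluded))
    return FeatureRanking(ser, layers, tuple(excluded), statistic)


def select_top_k(r: FeatureRanking, k: int, layers=None) -> list[str]:
    """The k highest-scoring features among the requested layers, ties at
    the boundary broken by ascending feature id.  Returns all candidates
    (with a warning) when fewer than k exist."""
    if k < 1:
        raise PreprocessError("k must be >= 1")
    if layers is None:
        candidates = list(r.scores.index)
    else:
        layers = set(layers)
        candidates = [f for f in r.scores.index if r.layers[f] in layers]
    candidates.sort(key=lambda f: (-r.scores[f], f))
    if len(candidates) < k:
        log.warning("select_top_k: only %d features available for k=%d", len(candidates), k)
        return candidates
    return candidates[:k]


def assemble_joint(m_t: OmicsMatrix, m_m: OmicsMatrix, selected,
                   ranking: FeatureRanking | None = None, k: int | None = None) -> JointMatrix:
    """Stack the selected transcript and metabolite rows and z-score each
    feature across columns (sample columns must match exactly)."""
    if list(m_t.sample_ids) != list(m_m.sample_ids):
        raise PreprocessError("transcript and metabolite matrices have different sample columns")
    selected = set(selected)
    rows, layers = [], {}
    for m in (m_t, m_m):
        keep = [f for f in m.feature_ids if f in selected]
        rows.append(m.values.loc[keep])
        for f in keep:
            layers[f] = m.layer_of(f)
    stacked = pd.concat(rows, axis=0)
    found = set(stacked.index)
    missing = selected - found
    if missing:
        raise PreprocessError(f"selected features absent from inputs: {sorted(missing)[:5]}")
    z = pd.DataFrame(index=stacked.index, columns=stacked.columns, dtype=float)
    for fid, row in stacked.iterrows():
        sd = row.std(ddof=1, skipna=True)
        if not np.isfinite(sd) or sd == 0:
            raise PreprocessError(f"feature {fid} is constant; cannot standardise")
        z.loc[fid] = (row - row.mean(skipna=True)) / sd
    return JointMatrix(z, pd.Series(layers).loc[z.index], ranking, k)
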