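"""Ordination and differential statistics.

PCA is the standard SVD of the centred (optionally unit-scaled) data
matrix, with a deterministic sign convention.  Differential testing is a
per-feature Welch two-sample t-test within each design stratum, with
Benjamini–Hochberg adjustment pooled across all tests of a contrast and a
two-tier significance code: ``*`` for q < 0.05 and ``**`` for q < 0.005
(a feature is reported ``*`` only when ``**`` is not met).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix, SampleDesign

log = logging.getLogger(__name__)

TIER_THRESHOLDS = (0.05, 0.005)  # "*", "**"


class StatsError(ValueError):
    pass


@dataclass
class PcaResult:
    scores: pd.DataFrame                    # samples x components (PC1..)
    loadings: pd.DataFrame                  # features x components
    explained_variance_fraction: np.ndarray


def pca(m: OmicsMatrix | pd.DataFrame, center: bool = True, unit_scale: bool = True,
        n_components: int | None = None) -> PcaResult:
    """Principal component analysis of a features x samples matrix via SVD
    of the sample x feature data.  Missing values are imputed by the
    feature mean (logged).  Sign convention: the largest-magnitude loading
    of each component is positive."""
    values = m.values if isinstance(m, OmicsMatrix) else m
    if values.shape[1] < 2 or values.shape[0] < 1:
        raise StatsError("PCA needs at least 2 samples and 1 feature")
    x = values.to_numpy(dtype=float).T  # samples x features
    if np.isnan(x).any():
        n_imputed = int(np.isnan(x).sum())
        log.info("pca: imputing %d missing value(s) by feature mean", n_imputed)
        col_mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = np.take(col_mean, idx[1])
    if center:
        x = x - x.mean(axis=0)
    if unit_scale:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.any():
            raise StatsError("all features constant; PCA undefined")
        if not keep.all():
            log.warning("pca: dropping %d constant feature(s)", int((~keep).sum()))
        x = x[:, keep] / sd[keep]
        feat_index = values.index[keep]
    else:
        if not (x.std(axis=0) > 0).any():
            raise StatsError("all features constant; PCA undefined")
        feat_index = values.index
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    k = len(s) if n_components is None else min(n_components, len(s))
    u, s, vt, frac = u[:, :k], s[:k], vt[:k], frac[:k]
    # deterministic signs: largest |loading| positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    comp = [f"PC{i}" for i in range(1, k + 1)]
    scores = pd.DataFrame(u * s, index=values.columns, columns=comp)
    loadings = pd.DataFrame(vt.T, index=feat_index, columns=comp)
    return PcaResult(scores, loadings, frac)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), in the
    input order: q(i) = min_{j>=i} p(j)*m/j on the sorted scale."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tier(q: float) -> str:
    if not np.isfinite(q):
        return "untestable"
    if q < TIER_THRESHOLDS[1]:
        return "**"
    if q < TIER_THRESHOLDS[0]:
        return "*"
    return "ns"


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t on non-missing values; degenerate zero-variance
    groups handled explicitly (identical groups -> p = 1)."""
    if x.size < 2 or y.size < 2:
        return np.nan, np.nan
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        return (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def differential_test(m: OmicsMatrix, d: SampleDesign, factor: str,
                      group_a: str, group_b: str,
                      stratify_by: tuple[str, ...] = ("stage", "treatment")) -> pd.DataFrame:
    """Per-feature, per-stratum Welch t-test of ``group_a`` vs ``group_b``
    on the given design factor (e.g. mutant vs wild-type genotype).

    Returns a tidy table with one row per (feature, stratum): test
    statistic, raw p, BH q (pooled over every testable row of the
    contrast) and tier.  Strata where either group has fewer than two
    non-missing replicates are flagged ``untestable`` rather than dropped.
    """
    if factor not in d.table.columns:
        raise StatsError(f"unknown design factor {factor!r}")
    absent = [s for s in m.sample_ids if s not in d.table.index]
    if absent:
        raise StatsError(f"samples absent from design: {absent[:5]}")
    sub = d.table.loc[m.sample_ids]
    strata = sorted(set(map(tuple, sub[list(stratify_by)].itertuples(index=False))))
    rows = []
    for stratum in strata:
        mask = np.ones(len(sub), dtype=bool)
        for col, val in zip(stratify_by, stratum):
            mask &= (sub[col] == val).to_numpy()
        ids_a = sub.index[mask & (sub[factor] == group_a).to_numpy()]
        ids_b = sub.index[mask & (sub[factor] == group_b).to_numpy()]
        if len(ids_a) == 0 or len(ids_b) == 0:
            continue  # contrast not present in this stratum (e.g. missing arm)
        va = m.values[ids_a].to_numpy(dtype=float)
        vb = m.values[ids_b].to_numpy(dtype=float)
        label = "/".join(str(v) for v in stratum)
        for i, fid in enumerate(m.feature_ids):
            x = va[i][np.isfinite(va[i])]
            y = vb[i][np.isfinite(vb[i])]
            t, p = _welch(x, y)
            rows.append((fid, label, t, p))
    out = pd.DataFrame(rows, columns=["feature_id", "stratum", "statistic", "p"])
    out["contrast"] = f"{factor}:{group_a}-vs-{group_b}"
    out["q"] = np.nan
    testable = out["p"].notna()
    if testable.any():
        out.loc[testable, "q"] = bh_fdr(out.loc[testable, "p"].to_numpy())
    out["tier"] = [tier(q) for q in out["q"]]
    return out[["feature_id", "stratum", "contrast", "statistic", "p", "q", "tier"]]
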