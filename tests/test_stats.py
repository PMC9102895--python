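import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fruitset_wcna as fw
from fruitset_wcna.io import OmicsMatrix, SampleDesign
from fruitset_wcna.stats import StatsError, tier

from oracles import bh_stepup


def _matrix(arr, layer="hormone", columns=None):
    df = pd.DataFrame(arr, index=[f"f{i}" for i in range(len(arr))],
                      columns=columns)
    return OmicsMatrix(df.astype(float), pd.DataFrame({"layer": layer}, index=df.index))


# ---------------------------------------------------------------- PCA

def test_pca_single_varying_feature_owns_all_variance():
    arr = np.ones((3, 6))
    arr[1] = [1, 2, 3, 4, 5, 6]
    res = fw.pca(_matrix(arr), unit_scale=False)
    assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_explained_fraction_on_known_covariance():
    """Data colored to have sample covariance exactly [[2,1],[1,2]]
    (eigenvalues 3 and 1) must split variance 75% / 25%."""
    rng = np.random.default_rng(1)
    n = 500
    x = rng.normal(size=(n, 2))
    x -= x.mean(axis=0)
    # whiten empirically, then color with chol([[2,1],[1,2]])
    cov = np.cov(x.T)
    white = x @ np.linalg.inv(np.linalg.cholesky(cov)).T
    data = white @ np.linalg.cholesky([[2.0, 1.0], [1.0, 2.0]]).T
    res = fw.pca(_matrix(data.T, columns=range(n)), unit_scale=False)
    assert res.explained_variance_fraction[0] == pytest.approx(0.75, abs=1e-6)
    assert res.explained_variance_fraction[1] == pytest.approx(0.25, abs=1e-6)


def test_pca_duplicating_samples_keeps_fractions():
    rng = np.random.default_rng(2)
    arr = rng.normal(size=(5, 8))
    res1 = fw.pca(_matrix(arr), unit_scale=False)
    res2 = fw.pca(_matrix(np.hstack([arr, arr]), columns=range(16)), unit_scale=False)
    assert np.allclose(res1.explained_variance_fraction,
                       res2.explained_variance_fraction, atol=1e-9)


def test_pca_invariants_scores_orthogonal_fractions_sum_to_one():
    rng = np.random.default_rng(3)
    arr = rng.normal(size=(6, 10))
    res = fw.pca(_matrix(arr), unit_scale=True)
    frac = res.explained_variance_fraction
    assert np.all(np.diff(frac) <= 1e-12)
    assert frac.sum() == pytest.approx(1.0, abs=1e-9)
    gram = res.scores.to_numpy().T @ res.scores.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8
    # reconstruction from all components equals the standardized input
    x = arr.T - arr.T.mean(axis=0)
    x /= x.std(axis=0, ddof=1)
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.abs(recon - x).max() < 1e-8


def test_pca_sign_convention_is_deterministic():
    rng = np.random.default_rng(4)
    arr = rng.normal(size=(4, 7))
    res = fw.pca(_matrix(arr))
    for col in res.loadings.columns:
        v = res.loadings[col].to_numpy()
        assert v[np.argmax(np.abs(v))] > 0


def test_pca_rejects_constant_matrix():
    with pytest.raises(StatsError):
        fw.pca(_matrix(np.ones((3, 5))))


# ---------------------------------------------------------------- BH

def test_bh_single_and_hand_example():
    assert fw.bh_fdr([0.03])[0] == pytest.approx(0.03, abs=1e-15)
    q = fw.bh_fdr([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03], atol=1e-15)


def test_bh_matches_stepup_oracle_on_random_vectors():
    rng = np.random.default_rng(5)
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.abs(fw.bh_fdr(p) - bh_stepup(p)).max() < 1e-12


def test_bh_rejects_out_of_range():
    with pytest.raises(StatsError):
        fw.bh_fdr([0.5, 1.2])


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
@settings(max_examples=80, deadline=None)
def test_bh_q_dominates_p(p):
    p = np.array(p)
    q = fw.bh_fdr(p)
    assert np.all(q >= p - 1e-15)
    assert np.all(q <= 1 + 1e-15)


def test_bh_threshold_equals_classical_rejection_set():
    """Thresholding q <= alpha reproduces the classical BH step-up
    rejection set (continuous p, so the boundary has measure zero)."""
    rng = np.random.default_rng(7)
    alpha = 0.1
    for _ in range(100):
        p = rng.uniform(size=50) ** 2  # some small values
        q = fw.bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        k_star = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= alpha * rank / m:
                k_star = rank
        classical = set(order[:k_star])
        assert {i for i in range(m) if q[i] <= alpha} == classical


# ---------------------------------------------------------------- differential

def _two_group(values_a, values_b):
    na, nb = len(values_a[0]), len(values_b[0])
    cols = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    arr = np.hstack([values_a, values_b])
    m = _matrix(arr, columns=cols)
    table = pd.DataFrame({
        "genotype": ["mut"] * na + ["wt"] * nb,
        "stage": 0, "treatment": "none",
        "replicate": list(range(1, na + 1)) + list(range(1, nb + 1)),
    }, index=pd.Index(cols, name="sample_id"))
    return m, SampleDesign(table)


def test_identical_groups_give_p_one():
    m, d = _two_group([[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]])
    out = fw.differential_test(m, d, "genotype", "mut", "wt")
    assert out.iloc[0]["p"] == pytest.approx(1.0)
    assert out.iloc[0]["tier"] == "ns"


def test_single_replicate_group_is_untestable_not_dropped():
    m, d = _two_group([[1.0]], [[1.0, 2.0, 3.0]])
    out = fw.differential_test(m, d, "genotype", "mut", "wt")
    assert len(out) == 1
    assert out.iloc[0]["tier"] == "untestable"
    assert np.isnan(out.iloc[0]["p"])


def test_large_shift_is_detected():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, size=(10, 5))
    b = rng.normal(0, 1, size=(10, 5))
    b[0] += 8.0
    m, d = _two_group(a, b)
    out = fw.differential_test(m, d, "genotype", "mut", "wt")
    row = out[out["feature_id"] == "f0"].iloc[0]
    assert row["tier"] in ("*", "**")
    assert out[out["feature_id"] != "f0"]["q"].min() > row["q"]


def test_missing_values_excluded_pairwise():
    m, d = _two_group([[1.0, 2.0, np.nan]], [[5.0, 6.0, 7.0]])
    out = fw.differential_test(m, d, "genotype", "mut", "wt")
    assert np.isfinite(out.iloc[0]["p"])  # tested on the 2 observed values


def test_tier_thresholds():
    assert tier(0.004) == "**"
    assert tier(0.02) == "*"
    assert tier(0.5) == "ns"
    assert tier(float("nan")) == "untestable"


def test_differential_tiers_reproduce_bh_over_contrast(small_dataset):
    h = fw.log_transform(small_dataset.matrices["hormone"], 1.0)
    out = fw.differential_test(h, small_dataset.design, "genotype", "mut", "wt")
    testable = out["p"].notna()
    q = bh_stepup(out.loc[testable, "p"].to_numpy())
    assert np.abs(out.loc[testable, "q"].to_numpy() - q).max() < 1e-12
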