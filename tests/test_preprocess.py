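import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fruitset_wcna as fw
from fruitset_wcna.io import OmicsMatrix
from fruitset_wcna.preprocess import FeatureRanking, PreprocessError


def _matrix(rows: dict, layer="transcript", columns=None):
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    if columns is not None:
        df.columns = columns
    meta = pd.DataFrame({"layer": layer}, index=df.index)
    return OmicsMatrix(df, meta)


# ---------------------------------------------------------------- log

def test_log_transform_values_and_missing():
    m = _matrix({"a": [0.0, 3.0], "b": [np.nan, 7.0]})
    out = fw.log_transform(m, offset=1.0)
    assert out.values.at["a", 0] == 0.0
    assert out.values.at["a", 1] == 2.0  # log2(4)
    assert np.isnan(out.values.at["b", 0])
    assert out.values.at["b", 1] == 3.0


def test_log_transform_rejects_negative():
    with pytest.raises(PreprocessError, match="negative"):
        fw.log_transform(_matrix({"a": [-1.0, 2.0]}))


@given(st.floats(0, 1e6), st.floats(0, 1e6))
@settings(max_examples=50, deadline=None)
def test_log_transform_is_monotone(x, y):
    if x > y:
        x, y = y, x
    out = fw.log_transform(_matrix({"a": [x, y]}), 1.0).values
    assert out.at["a", 0] <= out.at["a", 1]


# ---------------------------------------------------------------- cell means

def test_cell_means_averages_replicates(toy_matrix, toy_design):
    out = fw.cell_means(toy_matrix, toy_design)
    assert list(out.values.columns) == ["mut_0_none", "wt_0_none"]
    assert out.values.at["f1", "mut_0_none"] == 1.5
    # f2 has one ND replicate in the mut cell: mean of observed values
    assert out.values.at["f2", "mut_0_none"] == 4.0


def test_cell_means_all_nd_cell_stays_missing(toy_design):
    m = _matrix({"f": [np.nan, np.nan, 2.0]}, columns=["s1", "s2", "s3"])
    out = fw.cell_means(m, toy_design)
    assert np.isnan(out.values.at["f", "mut_0_none"])
    assert out.values.at["f", "wt_0_none"] == 2.0


def test_cell_means_column_count_equals_occupied_cells(small_dataset):
    m = fw.log_transform(small_dataset.matrices["transcript"], 1.0)
    out = fw.cell_means(m, small_dataset.design)
    n_cells = len(small_dataset.spec.design_cells())
    assert out.values.shape[1] == n_cells


def test_cell_means_requires_design_coverage(toy_matrix):
    partial = fw.SampleDesign(pd.DataFrame(
        {"genotype": ["m"], "stage": [0], "treatment": ["none"], "replicate": [1]},
        index=pd.Index(["s1"], name="sample_id")))
    with pytest.raises(PreprocessError, match="absent"):
        fw.cell_means(toy_matrix, partial)


# ---------------------------------------------------------------- MAD

def test_mad_simple_values():
    m = _matrix({"const": [1.0, 1.0, 1.0, 1.0], "pair": [0.0, 2.0, np.nan, np.nan]})
    r = fw.mad_scores(m)
    assert r.scores["const"] == 0.0
    assert r.scores["pair"] == 1.0  # mean 1, deviations {1, 1}


def test_mad_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    values = rng.normal(size=(500, 20))
    m = _matrix({f"f{i:03d}": values[i] for i in range(500)})
    r = fw.mad_scores(m)
    for i in (0, 7, 123, 499):
        fid = f"f{i:03d}"
        row = values[i]
        expected = sum(abs(v - row.mean()) for v in row) / len(row)
        assert abs(r.scores[fid] - expected) < 1e-12


def test_mad_excludes_sparse_features():
    m = _matrix({"good": [1.0, 2.0, 3.0, 4.0], "sparse": [1.0, np.nan, np.nan, np.nan]})
    r = fw.mad_scores(m)
    assert "sparse" in r.excluded
    assert "sparse" not in r.scores.index


def test_median_mad_variant():
    m = _matrix({"f": [0.0, 1.0, 2.0, 100.0]})
    r = fw.mad_scores(m, statistic="median")
    assert r.scores["f"] == 1.0  # median 1.5, |dev| = {1.5, .5, .5, 98.5} -> median 1


# ---------------------------------------------------------------- top-k

def _ranking(scores: dict, layers=None):
    ser = pd.Series(scores, dtype=float)
    lay = pd.Series({f: (layers or {}).get(f, "transcript") for f in ser.index})
    return FeatureRanking(ser, lay, ())


def test_select_top_k_basic_and_ties():
    r = _ranking({"a": 3.0, "b": 1.0, "c": 2.0})
    assert fw.select_top_k(r, 2) == ["a", "c"]
    tie = _ranking({"a": 2.0, "b": 2.0, "c": 5.0})
    assert fw.select_top_k(tie, 2) == ["c", "a"]  # boundary tie -> ascending id


def test_select_top_k_k_exceeds_n():
    r = _ranking({"a": 3.0, "b": 1.0})
    assert set(fw.select_top_k(r, 10)) == {"a", "b"}


def test_select_top_k_layer_filter():
    r = _ranking({"t1": 5.0, "m1": 4.0, "h1": 99.0},
                 layers={"t1": "transcript", "m1": "metabolite", "h1": "hormone"})
    assert fw.select_top_k(r, 2, layers={"transcript", "metabolite"}) == ["t1", "m1"]


@given(st.lists(st.tuples(st.text("ab", min_size=1, max_size=4),
                          st.floats(0, 100, allow_nan=False)), min_size=1, max_size=20,
                unique_by=lambda t: t[0]),
       st.integers(1, 25))
@settings(max_examples=60, deadline=None)
def test_select_top_k_size_and_permutation_invariance(items, k):
    scores = dict(items)
    r1 = _ranking(scores)
    r2 = _ranking(dict(reversed(items)))
    assert fw.select_top_k(r1, k) == fw.select_top_k(r2, k)
    assert len(fw.select_top_k(r1, k)) == min(k, len(scores))


# ---------------------------------------------------------------- joint

def test_assemble_joint_standardizes():
    t = _matrix({"t1": [1.0, 2.0, 3.0], "t2": [5.0, 1.0, 0.0]})
    m = _matrix({"m1": [2.0, 2.0, 8.0]}, layer="metabolite")
    joint = fw.assemble_joint(t, m, {"t1", "t2", "m1"})
    assert joint.values.shape == (3, 3)
    assert np.allclose(joint.values.mean(axis=1), 0, atol=1e-9)
    assert np.allclose(joint.values.std(axis=1, ddof=1), 1, atol=1e-9)
    assert set(joint.layers) == {"transcript", "metabolite"}


def test_assemble_joint_rejects_constant_feature():
    t = _matrix({"t1": [1.0, 1.0, 1.0]})
    m = _matrix({"m1": [2.0, 3.0, 8.0]}, layer="metabolite")
    with pytest.raises(PreprocessError, match="t1"):
        fw.assemble_joint(t, m, {"t1", "m1"})


def test_assemble_joint_rejects_column_mismatch():
    t = _matrix({"t1": [1.0, 2.0]}, columns=["a", "b"])
    m = _matrix({"m1": [1.0, 2.0]}, columns=["a", "c"], layer="metabolite")
    with pytest.raises(PreprocessError, match="sample"):
        fw.assemble_joint(t, m, {"t1", "m1"})


def test_zscoring_preserves_correlations():
    rng = np.random.default_rng(0)
    raw = rng.normal(size=(4, 10)) * [[1], [10], [100], [3]] + [[5], [0], [-7], [2]]
    t = _matrix({f"t{i}": raw[i] for i in range(4)})
    m = _matrix({"m1": rng.normal(size=10)}, layer="metabolite")
    joint = fw.assemble_joint(t, m, {f"t{i}" for i in range(4)})
    r_before = np.corrcoef(raw)
    r_after = np.corrcoef(joint.values.to_numpy())
    assert np.allclose(r_before, r_after, atol=1e-12)
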