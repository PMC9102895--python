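import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fruitset_wcna as fw

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """One generated single-pair dataset shared by read-only tests."""
    return fw.generate(fw.small_spec(seed=11))


@pytest.fixture()
def toy_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, np.nan, 6.0]],
        index=["f1", "f2"], columns=["s1", "s2", "s3"])
    meta = pd.DataFrame({"layer": "transcript"}, index=values.index)
    return fw.OmicsMatrix(values, meta)


@pytest.fixture()
def toy_design():
    table = pd.DataFrame(
        {"genotype": ["mut", "mut", "wt"], "stage": [0, 0, 0],
         "treatment": ["none", "none", "none"], "replicate": [1, 2, 1]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"))
    return fw.SampleDesign(table)
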