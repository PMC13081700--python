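import numpy as np
import pandas as pd
import pytest

from netdom import ImagingMatrix, PhenotypeDesign


def make_dataset(n_subjects=30, n_locations=60, seed=0, nuisance=True, mask=None):
    """Small i.i.d. Gaussian dataset with a matched design (target 'x')."""
    rng = np.random.default_rng(seed)
    cols = {"x": rng.standard_normal(n_subjects)}
    nuis = ()
    if nuisance:
        cols["age"] = rng.standard_normal(n_subjects)
        cols["sex"] = rng.binomial(1, 0.5, n_subjects).astype(float)
        nuis = ("age", "sex")
    design = PhenotypeDesign(pd.DataFrame(cols), target="x", nuisance=nuis)
    Y = rng.standard_normal((n_subjects, n_locations))
    return ImagingMatrix(Y, mask=mask), design


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
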