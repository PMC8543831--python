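import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hotregion.features import FeatureTable
from hotregion.synthetic import SyntheticSpec, generate_dataset


def make_table(x: np.ndarray, labels, names=None) -> FeatureTable:
    """Build a FeatureTable from a plain matrix for classifier/selection tests."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    names = names or [f"f{j}" for j in range(x.shape[1])]
    sites = [("CPLX", "A", i + 1) for i in range(x.shape[0])]
    return FeatureTable(pd.DataFrame(x, columns=names), np.asarray(labels, dtype=int), sites)


@pytest.fixture(scope="session")
def recovery_dataset():
    """The well-separated synthetic benchmark: 2 complexes, 2 planted regions
    each, 3-sigma feature separation, zero label noise, seed 17."""
    spec = SyntheticSpec()
    return spec, generate_dataset(spec, seed=17)
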