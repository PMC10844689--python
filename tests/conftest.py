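import numpy as np
import pandas as pd
import pytest

import morphokit as mk
from morphokit.core import FactorTable, ShapeDataset


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study (3 clones x 2 instars x 6 risks x 4 reps)."""
    data, truth = mk.simulate(mk.default_spec(replicates=4), seed=1)
    return data, truth


@pytest.fixture(scope="session")
def aligned_study(small_study):
    data, truth = small_study
    return mk.gpa(data).aligned, truth


def make_aligned(coords, factors=None, **kwargs):
    """Wrap raw coordinates as an (already) aligned dataset for unit tests."""
    coords = np.asarray(coords, dtype=float)
    ids = tuple(f"s{i}" for i in range(coords.shape[0]))
    ft = None
    if factors is not None:
        ft = FactorTable(pd.DataFrame({"specimen": list(ids), **factors}))
    return ShapeDataset(coords, ids, factors=ft, aligned=True, **kwargs)


@pytest.fixture
def triangle():
    return np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 1.0]])
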