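import warnings

import numpy as np
import pandas as pd
import pytest

from facomp.synthetic_data import SyntheticStudyConfig, generate_density_tables
from facomp.tables import DensityTable

warnings.filterwarnings("ignore", message=".*nearly constant.*")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study_config():
    """A reduced six-dataset study used by several module tests."""
    return SyntheticStudyConfig(n_cells=3, adhesions_per_cell=40, seed=7)


@pytest.fixture(scope="session")
def study_tables(small_study_config):
    return generate_density_tables(small_study_config)


def make_table(arrays: dict, dataset_id="R1O1", **meta) -> DensityTable:
    """Build a minimal DensityTable from component -> values arrays."""
    data = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in arrays.items()})
    data.insert(0, "adhesion_id", np.arange(1, len(data) + 1))
    return DensityTable(
        data=data, components=tuple(arrays), dataset_id=dataset_id, **meta
    )
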