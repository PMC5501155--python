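import numpy as np
import pytest

from maxenm import (
    GridSpec,
    Layer,
    RasterStack,
    SyntheticConfig,
    build_landscape,
    thin_occurrences,
)


@pytest.fixture(scope="session")
def small_config():
    """A reduced landscape used by unit tests (fast, still structured)."""
    return SyntheticConfig(n_cols=100, n_rows=100, n_presences=100, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return build_landscape(small_config)


@pytest.fixture(scope="session")
def small_thinned(small_dataset):
    return thin_occurrences(small_dataset.occurrences, seed=7)


@pytest.fixture()
def unit_spec():
    """10 x 8 grid of 250 m cells with origin at (0, 2000)."""
    return GridSpec(n_cols=10, n_rows=8, cell_size=250.0, origin_x=0.0, origin_y=2000.0)


@pytest.fixture()
def constant_stack(unit_spec):
    vals = np.ma.asarray(np.full((8, 10), 7.0))
    return RasterStack(unit_spec, [Layer("const7", vals)])
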