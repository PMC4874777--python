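import numpy as np
import pytest

from tauseq import geometry as geo
from tauseq import synthetic as syn


@pytest.fixture(scope="session")
def straight_cell():
    """A 3 x 1 µm straight spherocylinder with exact dimensions."""
    spec = syn.CellSimSpec(
        length_um=(3.0, 0.0), width_um=(1.0, 0.0), n_cells=1, seed=1
    )
    return syn.simulate_cells(spec)[0]


@pytest.fixture(scope="session")
def straight_cs(straight_cell):
    return geo.build_coordinate_system(geo.CellBoundary(straight_cell.boundary))


@pytest.fixture(scope="session")
def toy_proteome():
    records, annotation = syn.simulate_proteome(150, seed=11)
    return records, annotation


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
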