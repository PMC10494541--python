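import numpy as np
import pytest

from fcnet.connectivity import ConnectivityMatrix, ParcelAtlas, SubjectTimeSeries
from fcnet.synthetic import ModularCovSpec


@pytest.fixture
def small_spec():
    """6 parcels in 2 modules of 3; segregated correlation structure."""
    return ModularCovSpec(
        n_parcels=6,
        module_assignment=(0, 0, 0, 1, 1, 1),
        within_r=0.6,
        between_r=0.1,
        n_timepoints=640,
    )


@pytest.fixture
def toy_ts():
    rng = np.random.default_rng(7)
    return SubjectTimeSeries(
        values=rng.standard_normal((50, 5)),
        parcel_ids=tuple(f"p{i}" for i in range(5)),
        subject_id="toy",
    )


@pytest.fixture
def toy_atlas():
    ids = tuple(f"p{i}" for i in range(5))
    nets = dict(zip(ids, ["A", "A", "A", "B", "B"]))
    return ParcelAtlas(parcel_ids=ids, network_of=nets)


def symmetric_matrix(n: int, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, n))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


@pytest.fixture
def random_cm():
    z = symmetric_matrix(8, seed=3)
    return ConnectivityMatrix(
        z=z, parcel_ids=tuple(f"p{i}" for i in range(8)), subject_id="rand"
    )
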