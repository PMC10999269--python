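import numpy as np
import pytest

from sedadyn import DriverSeries, MetacommunityParams, NicheParams
from sedadyn.scenarios import generate_records, make_scenario


@pytest.fixture
def logistic_params():
    """S=1, L=1 logistic configuration: r = 1, K = 1 under a flat driver."""
    return MetacommunityParams(
        n_species=1,
        n_sites=1,
        growth=NicheParams(r=[1.0], mu=[0.0], sigma=[1.0], b0=[0.0]),
        alpha=[[1.0]],
    )


@pytest.fixture
def flat_driver():
    return [DriverSeries([0.0, 100.0], [0.0, 0.0])]


@pytest.fixture
def two_species_params():
    """Two competitors, no trophic links, no dispersal, one site."""
    return MetacommunityParams(
        n_species=2,
        n_sites=1,
        growth=NicheParams(
            r=[1.0, 0.5], mu=[0.0, 0.0], sigma=[1.0, 1.0], b0=[0.0, 0.0]
        ),
        alpha=[[0.1, 0.05], [0.02, 0.1]],
    )


@pytest.fixture(scope="session")
def trio_data():
    """The 3-species / 2-site scenario with its generated records."""
    sc = make_scenario("trio", seed=1)
    records, traj = generate_records(sc)
    return sc, records, traj
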