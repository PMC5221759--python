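import numpy as np
import pytest

from spikelet_lab.cells import build_passive_validation_cell, build_reduced_cell
from spikelet_lab.engine import discretize
from spikelet_lab.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def reduced_graph():
    return discretize(build_reduced_cell())


@pytest.fixture(scope="session")
def passive_graph():
    return discretize(build_passive_validation_cell())


def standard_schedule(n_spikelets=5, n_aps=3, spacing=40.0, t0=50.0):
    n = n_spikelets + n_aps
    return [
        (t0 + spacing * i, "spikelet" if i < n_spikelets else "sh_AP")
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def quiet_fixture():
    """Low-noise synthetic traces with 5 spikelets and 3 APs."""
    spec = FixtureSpec(T=400.0, noise_sd=0.5, schedule=standard_schedule())
    return make_fixture(spec, seed=7)
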