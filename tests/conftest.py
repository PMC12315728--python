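import numpy as np
import pytest

from sgmfmri import (
    FrequencyGrid,
    SGMParams,
    SyntheticCohortSpec,
    eigendecompose,
    fixture_cohort,
    normalize_connectome,
    scale_to_critical_coupling,
)


def random_connected_connectome(n, seed, density=0.4):
    """Random symmetric connected weighted graph, sum-normalized."""
    rng = np.random.default_rng(seed)
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    w = w + w.T
    # spanning backbone to guarantee connectivity
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        if w[a, b] == 0:
            w[a, b] = w[b, a] = 0.05 + rng.random()
    return normalize_connectome(w)


@pytest.fixture(scope="session")
def toy2():
    """Two-region toy with weights [[0, .5], [.5, 0]]."""
    return normalize_connectome(np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture(scope="session")
def sc10():
    return random_connected_connectome(10, seed=42)


@pytest.fixture(scope="session")
def eig10(sc10):
    return eigendecompose(sc10, 0.8)


@pytest.fixture(scope="session")
def grid():
    return FrequencyGrid.from_band(0.01, 0.25, 40)


@pytest.fixture(scope="session")
def params():
    return SGMParams(alpha=0.8, tau=2.0)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (shared across tests: generation is cheap,
    fits are not)."""
    return fixture_cohort(SyntheticCohortSpec())


@pytest.fixture(scope="session")
def scaled_sc(default_cohort):
    return scale_to_critical_coupling(default_cohort.connectomes[0])
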