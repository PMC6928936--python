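import numpy as np
import pytest

import eegsr


@pytest.fixture(scope="session")
def montage():
    return eegsr.default_montage()


@pytest.fixture(scope="session")
def head():
    return eegsr.HeadModel()


@pytest.fixture(scope="session")
def grid(head):
    return eegsr.build_source_grid(head, spacing_mm=5.0)


@pytest.fixture(scope="session")
def leadfield(grid, montage, head):
    return eegsr.compute_leadfield(grid.positions_normalized, montage, head)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_trials(montage, head):
    """Small noiseless two-dipole dataset shared across tests."""
    return eegsr.simulate_clean_trials(eegsr.default_dipoles(), montage, head,
                                       n_trials=4)
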