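import pytest

from seqcost import calibrated_inventory, compute_matrix, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def calibrated(params):
    return calibrated_inventory()


@pytest.fixture(scope="session")
def base_matrix(calibrated, params):
    return compute_matrix(calibrated, params)
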