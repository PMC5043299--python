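import pytest

from crimedyn import equilibrium_E4, make_default_parameters, sample_parameters


@pytest.fixture(scope="session")
def defaults():
    """Base parameter set used for all reference results."""
    return make_default_parameters()


@pytest.fixture(scope="session")
def e4(defaults):
    """The unique coexistence equilibrium at the base parameters."""
    records = equilibrium_E4(defaults)
    assert len(records) == 1
    return records[0]


@pytest.fixture(scope="session")
def sampled_params():
    """Fifty valid parameter sets drawn from the default sampling box."""
    return sample_parameters(seed=11, n=50)
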