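import pytest

from cernet.synthetic import SimConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One shared synthetic study under the default conditions."""
    return generate_study(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_truth(default_study):
    return default_study.truth
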