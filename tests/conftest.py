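import pytest

from ricesim import GeneratorConfig, generate


@pytest.fixture(scope="session")
def japan_params():
    """The packaged japan_like calibration (seed 0), shared read-only."""
    return generate(GeneratorConfig(seed=0, mode="japan_like"))


@pytest.fixture()
def japan_params_copy(japan_params):
    return japan_params.copy()


@pytest.fixture(scope="session")
def random_params():
    """One arbitrary valid parameter set for structure-agnostic tests."""
    return generate(GeneratorConfig(seed=7, mode="random_valid"))
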