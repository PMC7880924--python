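import pytest

from stentcea import ModelOptions, ParameterSet


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    """Published base-case inputs."""
    return ParameterSet()


@pytest.fixture(scope="session")
def default_options() -> ModelOptions:
    return ModelOptions()
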