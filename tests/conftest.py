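import pytest
from hypothesis import settings

from nucleome3d.builder import BuilderConfig, build_genome_model

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model_100k():
    """A 100 kbp single-chromosome model with default parameters."""
    return build_genome_model({"chrA": 100_000}, BuilderConfig(seed=11))


@pytest.fixture(scope="session")
def model_1m():
    """A 1 Mbp single-chromosome model with default parameters."""
    return build_genome_model({"chr1": 1_000_000}, BuilderConfig(seed=5))
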