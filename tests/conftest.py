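import pytest

from pnpkit.processing import ProcessingConfig
from pnpkit.simulate import GeneratorConfig, generate_precursor_set


@pytest.fixture(scope="session")
def default_config() -> ProcessingConfig:
    return ProcessingConfig()


@pytest.fixture(scope="session")
def small_synthetic_set():
    """50 synthetic precursors with ground truth (seed 3 conditions)."""
    config = GeneratorConfig(n_precursors=50, seed=3)
    transcripts, proteins, truth = generate_precursor_set(config)
    return config, transcripts, proteins, truth


@pytest.fixture(scope="session")
def full_synthetic_set():
    """The 200-precursor benchmark set (seed 3)."""
    config = GeneratorConfig(n_precursors=200, seed=3)
    transcripts, proteins, truth = generate_precursor_set(config)
    return config, transcripts, proteins, truth
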