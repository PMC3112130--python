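import pytest

from twinliab.simulate import paper_combined, simulate


@pytest.fixture(scope="session")
def preset_config():
    return paper_combined()


@pytest.fixture(scope="session")
def preset_dataset(preset_config):
    """One paper-scale synthetic two-cohort dataset (seed 1)."""
    return simulate(preset_config, seed=1)
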