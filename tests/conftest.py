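import pytest

from ambidense.simulate import GenomeSpec, build_ambisense_genome


@pytest.fixture(scope="session")
def default_truth():
    """One default synthetic genome shared across the suite (seed fixed)."""
    return build_ambisense_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def default_genome(default_truth):
    return default_truth.genome
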