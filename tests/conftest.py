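import numpy as np
import pytest

from csflmd.simulate import make_genome_bins, uniform_genome


@pytest.fixture(scope="session")
def small_bins():
    """Six 10 Mb autosomes -> 60 bins; cheap unit-test genome."""
    return make_genome_bins(uniform_genome(6, 10_000_000), seed=1)


@pytest.fixture(scope="session")
def mid_bins():
    """22 x 20 Mb -> 440 bins; for recovery-style tests."""
    return make_genome_bins(uniform_genome(22, 20_000_000), seed=1)


@pytest.fixture(scope="session")
def full_bins():
    """22 x 100 Mb -> 2200 bins; the study-scale genome."""
    return make_genome_bins(uniform_genome(22, 100_000_000), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
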