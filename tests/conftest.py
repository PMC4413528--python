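import numpy as np
import pytest

from facmine.simulate import GenomeSpec


@pytest.fixture
def small_genome() -> GenomeSpec:
    """A 3 Mb single-chromosome genome for fast fixtures."""
    return GenomeSpec({"chr1": 3_000_000}, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_917)
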