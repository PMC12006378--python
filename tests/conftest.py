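import numpy as np
import pytest

from mitostruct.core import CircularSequence, GenomeInterval
from mitostruct.repeats import RepeatPair
from mitostruct.simulate import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def sentinel_configuration(rng):
    """Toy two-chromosome genome with distinct 1 kb sentinel flanks around a
    shared 600 bp core; useful for configuration and classification tests."""
    L1, R1, L2, R2 = (random_sequence(rng, 1000) for _ in range(4))
    core = random_sequence(rng, 600)
    chr_a = CircularSequence("chrA", L1 + core + R1)
    chr_b = CircularSequence("chrB", L2 + core + R2)
    pair = RepeatPair(
        "R01",
        GenomeInterval("chrA", 1001, 1600, "+"),
        GenomeInterval("chrB", 1001, 1600, "+"),
        600,
        1.0,
        "direct",
    )
    return {
        "genome": [chr_a, chr_b],
        "pair": pair,
        "parts": {"L1": L1, "R1": R1, "L2": L2, "R2": R2, "core": core},
    }
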