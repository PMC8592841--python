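import numpy as np
import pytest

from rddmkit import Amplicon, Strand


@pytest.fixture
def small_amplicon() -> Amplicon:
    """40 evenly spaced CHH sites (CAT repeats), forward assayed strand."""
    return Amplicon("amp1", "AT" + "CAT" * 40 + "GG", Strand.FORWARD)


@pytest.fixture
def mixed_amplicon() -> Amplicon:
    """Amplicon with CG, CHG and CHH sites."""
    return Amplicon("mix1", "AACGTT" + "CAGT" * 5 + "CAT" * 10 + "ACGTA", Strand.FORWARD)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
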