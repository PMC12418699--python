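import numpy as np
import pytest

from cenarch.simulate import detection_fixture, random_family


@pytest.fixture(scope="session")
def fixture_genome():
    """Shared detection fixture: 10 compliant elements + 5 structural decoys."""
    seq, truth, decoys = detection_fixture(seed=0)
    return seq, truth, decoys


@pytest.fixture(scope="session")
def three_families():
    rng = np.random.default_rng(77)
    return [
        random_family(f"CRW{i + 1}", rng, ltr_len=400, internal_len=2500)
        for i in range(3)
    ]
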