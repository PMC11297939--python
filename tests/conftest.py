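import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def spawn_seeds(base: int, k: int) -> list[int]:
    """k reproducible child seeds below 2**31."""
    ss = np.random.SeedSequence(base)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(k)]
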