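import numpy as np
import pytest

from lekipm.lek_data import LekCountSeries


@pytest.fixture
def simple_series():
    """Three complete years at full effort."""
    return LekCountSeries(
        years=np.array([2000, 2001, 2002]),
        males=np.array([100.0, 110.0, 121.0]),
        lek_areas=np.array([20.0, 20.0, 20.0]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def derived_rng(entropy: int, *key: int) -> np.random.Generator:
    """Replicate-specific generator with a stable spawn key."""
    return np.random.default_rng(np.random.SeedSequence(entropy=entropy, spawn_key=key))
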