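import numpy as np
import pytest

from cryspect import generate_cohort, group_preset


def short_preset(group: str, **overrides):
    """Study preset shrunk to ~10 s recordings for fast unit tests."""
    spec = group_preset(group)
    spec.total_duration_range = (8.0, 12.0)
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


@pytest.fixture(scope="session")
def small_cohort():
    """6 M + 6 C short recordings shared across test modules."""
    return generate_cohort(short_preset("M"), short_preset("C"), 6, 6, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
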