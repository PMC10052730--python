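import numpy as np
import pandas as pd
import pytest

from pulmopt.datasets import CohortSpec, generate_cohort


class StubRng:
    """Deterministic stand-in for numpy Generator in single-step oracle
    tests: every uniform draw returns ``value``."""

    def __init__(self, value: float):
        self.value = float(value)

    def random(self, shape=None):
        if shape is None:
            return self.value
        return np.full(shape, self.value)

    def uniform(self, low=0.0, high=1.0, size=None):
        draw = low + self.value * (high - low)
        if size is None:
            return draw
        return np.full(size, draw)

    def normal(self, loc=0.0, scale=1.0, size=None):
        if size is None:
            return loc
        return np.full(size, loc)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(
        CohortSpec(n=120, effect_size=3.0, missing_rate=0.2, seed=7)
    )
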