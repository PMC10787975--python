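import numpy as np
import pytest

from potitecrm import ObservedData, build_adept_design, default_design


@pytest.fixture(scope="session")
def adept():
    """(grid, orderings, skeleton) of the six-dose design."""
    return build_adept_design()


@pytest.fixture(scope="session")
def design():
    return default_design()


def random_dataset(rng: np.random.Generator, k: int = 6, max_n: int = 15) -> ObservedData:
    """A random plausible patient snapshot: mixed doses, events, weights."""
    n = int(rng.integers(1, max_n + 1))
    dose = rng.integers(0, k, n)
    y = (rng.random(n) < 0.3).astype(int)
    w = np.where(y == 1, 1.0, np.round(rng.uniform(0.6, 1.0, n), 3))
    return ObservedData(tuple(int(d) for d in dose), tuple(int(v) for v in y), tuple(float(v) for v in w))
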