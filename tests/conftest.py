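import numpy as np
import pytest

from marginrad.prep import DiscretizedVolume


def random_discretized(rng, shape=(8, 8, 4), n_levels=8, fill=0.7, spacing=(1.0, 1.0, 1.0)):
    """A random small discretized volume with a random mask."""
    mask = rng.random(shape) < fill
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return DiscretizedVolume(levels, n_levels, mask, spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny deterministic phantom cohort shared across tests."""
    from marginrad.synthetic import PhantomConfig, generate_cohort

    cfg = PhantomConfig(n_cases=8, seed=42)
    return generate_cohort(cfg)
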