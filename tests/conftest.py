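import numpy as np
import pytest

from nodecad.phantom import PhantomConfig, generate_phantom


def small_phantom_config(seed: int = 0, **overrides) -> PhantomConfig:
    """A fast-to-generate phantom used across the suite."""
    kwargs = dict(
        grid_shape=(48, 48, 48),
        n_nodes=3,
        node_diameter_range_mm=(5.0, 9.0),
        n_vessels=2,
        n_sheets=1,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_phantom_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
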