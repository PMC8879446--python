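import numpy as np
import pytest

from mutualcl import DomainSpec, default_benchmark, generate_benchmark


@pytest.fixture(scope="session")
def bench3():
    """The bundled 3-domain, 3-increment benchmark (session-cached)."""
    return default_benchmark(seed=0)


@pytest.fixture(scope="session")
def bench_two_class():
    """A single-domain, two-well-separated-class benchmark."""
    spec = DomainSpec(
        name="d",
        channels=1,
        class_shapes={"a": "disc", "b": "bar"},
        noise_sigma=0.1,
        items_per_class=60,
    )
    return generate_benchmark([spec], [("d", ["a", "b"])], seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
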