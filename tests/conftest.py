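import numpy as np
import pytest

from porelock.fixtures import ToyPoreSpec, build_toy_pentamer


@pytest.fixture(scope="session")
def toy_spec() -> ToyPoreSpec:
    return ToyPoreSpec()


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    """Idealized symmetric pentamer, axis on lab z, 9' ring at s = 0."""
    return build_toy_pentamer(toy_spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
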