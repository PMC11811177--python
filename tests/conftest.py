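import numpy as np
import pytest

from boclahe.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def lesion_spec():
    return PhantomSpec(lesions=((70, 48, 7, 25.0),), noise_sigma=3.0)


@pytest.fixture(scope="session")
def phantom_triple(lesion_spec):
    return generate_phantom(lesion_spec, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_small_phantom(rng):
    """A small random phantom for oracle comparisons (<= 64x64)."""
    h = int(rng.integers(48, 65))
    w = int(rng.integers(48, 65))
    spec = PhantomSpec(
        width=w,
        height=h,
        background_level=float(rng.uniform(15, 50)),
        lung_fill=float(rng.uniform(90, 160)),
        rib_count=int(rng.integers(0, 6)),
        rib_amplitude=float(rng.uniform(0, 15)),
        noise_sigma=float(rng.uniform(0.5, 6)),
    )
    img, mask, _ = generate_phantom(spec, int(rng.integers(0, 2**31)))
    return img, mask
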