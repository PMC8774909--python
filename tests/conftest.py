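import numpy as np
import pytest

from deepwise import SynthConfig, generate_image


#: Desk-scale generator settings reused across test modules: small canvas and
#: smaller cells so placement and blending stay fast.
SMALL_SYNTH = dict(
    width=192,
    height=192,
    n_stained=(2, 4),
    n_unstained=(2, 4),
    stained_axes=(10, 18),
    unstained_axes=(6, 10),
)


@pytest.fixture(scope="session")
def small_train():
    """Three small synthetic annotated images used as a training set."""
    return [
        generate_image(SynthConfig(seed=seed, **SMALL_SYNTH))[0]
        for seed in (101, 102, 103)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob(rng, shape=(32, 32), n_seeds=4, n_grow=120):
    """A random connected blob mask grown from seed pixels (test helper)."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    r = rng.integers(4, shape[0] - 4)
    c = rng.integers(4, shape[1] - 4)
    mask[r, c] = True
    for _ in range(n_grow):
        frontier = ndimage.binary_dilation(mask) & ~mask
        rows, cols = np.nonzero(frontier)
        if rows.size == 0:
            break
        k = rng.integers(rows.size)
        mask[rows[k], cols[k]] = True
    return mask
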