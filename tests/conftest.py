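import numpy as np
import pytest

from stromaquant.simulate import (
    ImageSimParams,
    default_gating_config,
    default_threshold_config,
    generate_core_image,
)


@pytest.fixture(scope="session")
def noise_free_scene():
    """One noise-free synthetic core with its configs; reused across tests."""
    params = ImageSimParams(n_cells=50, noise_sd=0.0, n_speckles=0, seed=1)
    image, truth = generate_core_image(params)
    return {
        "params": params,
        "image": image,
        "truth": truth,
        "thresholds": default_threshold_config(params),
        "gating": default_gating_config(params),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(32, 32), p=0.35):
    return rng.random(shape) < p
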