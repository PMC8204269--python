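import numpy as np
import pytest

import brainstates as bs


@pytest.fixture(scope="session")
def tiny_gt():
    """A small 3-state world for fast unit tests."""
    return bs.make_ground_truth(
        {
            "K": 3,
            "n_parcels": 6,
            "n_subjects": 2,
            "n_samples": 4000,
            "state_freqs": (6.0, 12.0, 22.0),
            "parcels_per_state": 2,
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
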