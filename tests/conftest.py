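import dataclasses

import numpy as np
import pytest

from octinpaint import (PhantomSpec, TrainingConfig, collect_training_patches,
                        generate_phantom, ksvd_train)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_phantom():
    """A small layered speckle phantom (noisy, reference) for pipeline tests."""
    spec = dataclasses.replace(PhantomSpec(), height=96, width=96,
                               layer_boundaries=(15, 35, 60, 80),
                               layer_reflectivities=(180.0, 110.0, 150.0, 70.0),
                               seed=0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom_dict(small_phantom):
    """A compact dictionary trained on the small phantom's reference image."""
    _, ref = small_phantom
    Y = collect_training_patches([ref], (8, 8), max_patches=4000, seed=1)
    cfg = TrainingConfig(n_atoms=96, iterations=8, seed=1)
    return ksvd_train(Y, cfg)
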