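import numpy as np
import pytest

from msalnamd import (generate_labeled_set, make_lvc_model, normal_mode_data,
                      wigner_sample)
from msalnamd.units import FS_TO_AU_TIME

DT_01FS = 0.1 * FS_TO_AU_TIME


@pytest.fixture(scope="session")
def lvc_1atom_2state():
    """Small lab-frame model surface with a reachable avoided crossing."""
    return make_lvc_model(1, 2, seed=5)


@pytest.fixture(scope="session")
def lvc_3atom_3state():
    return make_lvc_model(3, 3, seed=1)


@pytest.fixture(scope="session")
def labeled_500(lvc_1atom_2state):
    """500 Wigner-sampled labeled points on the 1-atom 2-state surface."""
    nm = normal_mode_data(lvc_1atom_2state)
    samples = wigner_sample(nm, 500, seed=17)
    return generate_labeled_set(lvc_1atom_2state, [s.coords for s in samples])


@pytest.fixture(scope="session")
def trained_main(labeled_500):
    from msalnamd import TrainConfig, train

    model, history = train(
        labeled_500, "main", seed=3,
        schedule=TrainConfig(epochs=4000, patience=4000),
    )
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
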