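import numpy as np
import pytest

from glosstrans import synth


@pytest.fixture(scope="session")
def grid44():
    return synth.StimulusGrid(n_gloss=4, n_filter=4)


@pytest.fixture(scope="session")
def additive_observer():
    """The canonical additive ground truth used across recovery tests."""
    return synth.ObserverModel(psi_g=(0.0, 1.0, 2.0, 3.0), psi_r=(0.0, -0.2, -0.4, -0.6), sigma=1.0)


@pytest.fixture(scope="session")
def additive_trials_40reps(grid44, additive_observer):
    """A large responded session (40 repetitions, 4800 trials) for recovery."""
    design = synth.build_conjoint_design(grid44, repetitions=40, seed=11)
    return synth.simulate_conjoint_responses(design, additive_observer, seed=12)


@pytest.fixture()
def checker_image():
    rng = np.random.default_rng(42)
    img = rng.uniform(0.25, 0.75, size=(32, 32))
    img[0, 0], img[0, 1] = 0.2, 0.8  # pin the extremes -> contrast 0.6
    return img
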