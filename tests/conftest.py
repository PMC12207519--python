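import numpy as np
import pytest

import mwudyn as md


@pytest.fixture(scope="session")
def ex1_spec():
    return md.example1()


@pytest.fixture(scope="session")
def ex1_game(ex1_spec):
    """Example-1 baseline game (sigma = 1)."""
    return ex1_spec.to_game(sigma=1.0)


@pytest.fixture(scope="session")
def ex1_state(ex1_spec):
    return ex1_spec.initial_state()


@pytest.fixture(scope="session")
def ex1_ctx(ex1_game, ex1_state):
    return md.CurveContext.for_game(ex1_game, ex1_state)


@pytest.fixture(scope="session")
def ex2_spec():
    return md.example2()


def random_game_and_state(seed, m=None, a_range=(0.5, 30.0)):
    """Seeded random game + on-cube initial state for property tests."""
    rng = np.random.default_rng(seed)
    if m is None:
        m = int(rng.integers(1, 8))
    spec = md.random_population(m, a_range, seed=seed)
    return spec.to_game(sigma=1.0), spec.initial_state()
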