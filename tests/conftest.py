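import numpy as np
import pytest

from semigait import StateSpace, build_transition_mask, random_params


SMALL_SPACES = [
    StateSpace(r=1, tau=2, ell=1, kappa=1, w=2),   # 4 composite states
    StateSpace(r=2, tau=2, ell=1, kappa=1, w=2),   # 8
    StateSpace(r=1, tau=3, ell=0, kappa=2, w=1),   # 3, no semi-Markov part
    StateSpace(r=2, tau=2, ell=2, kappa=2, w=2),   # 12
    StateSpace(r=1, tau=4, ell=0, kappa=1, w=3),   # 4
]


def make_instance(space, seed, n):
    """Random valid params plus a simulated observation sequence."""
    from semigait import sample_model

    mask = build_transition_mask(space)
    params = random_params(space, mask, seed)
    path, obs = sample_model(params, space, n, seed=seed + 1)
    return params, mask, path, obs


@pytest.fixture
def small_space():
    return SMALL_SPACES[1]


@pytest.fixture
def small_instance(small_space):
    return make_instance(small_space, seed=7, n=50)
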