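import numpy as np
import pytest

import actionsym as a
from actionsym.primitive_matching import fit_primitive_templates


@pytest.fixture(scope="session")
def library():
    return a.make_primitive_library(5, seed=3)


@pytest.fixture(scope="session")
def foreign_library():
    return a.make_primitive_library(5, seed=99)


def _trials_for(library, seed, n_trials=20):
    rng = np.random.default_rng(seed)
    noise = a.StrokeNoise()
    return {
        p.primitive_id: [
            a.sample_stroke(p, rng.uniform(0, 300, 2), rng.uniform(100, 250),
                            noise, seed=int(rng.integers(2**31)))
            for _ in range(n_trials)
        ]
        for p in library
    }


@pytest.fixture(scope="session")
def single_shape_trials(library):
    return _trials_for(library, seed=0)


@pytest.fixture(scope="session")
def templates(single_shape_trials):
    return fit_primitive_templates(single_shape_trials)


@pytest.fixture(scope="session")
def foreign_templates(foreign_library):
    return fit_primitive_templates(_trials_for(foreign_library, seed=1))
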