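import numpy as np
import pytest

from bearclock.mcmc import Chain, ParamLayout
from bearclock.model import ModelSpec, ParameterState


def make_chain(spec: ModelSpec, states, n_animals: int, seed: int = 0) -> Chain:
    """Build a Chain directly from explicit ParameterStates (test scaffolding)."""
    layout = ParamLayout(spec, n_animals)
    draws = np.vstack([layout.vector(s) for s in states])
    return Chain(layout=layout, draws=draws, acceptance_rates={}, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
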