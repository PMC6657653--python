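import numpy as np
import pytest

from seqreplay import decoding, simulate, task


@pytest.fixture
def study1():
    return task.make_study_structure("study1")


@pytest.fixture
def small_patterns():
    """16 channels, 4 states — cheap decodable patterns."""
    return simulate.make_state_patterns(16, 4, seed=0, orthogonalize=True)


@pytest.fixture
def patterns8():
    return simulate.make_state_patterns(64, 8, seed=0)


@pytest.fixture
def localizer8(patterns8):
    return simulate.simulate_localizer(patterns8, 12, 0.2, seed=1)


@pytest.fixture
def decoders8(localizer8):
    return decoding.train_decoders(
        localizer8, simulate.null_examples(localizer8), seed=2
    )


def random_reactivation(n, s, seed, rate=100.0):
    rng = np.random.default_rng(seed)
    vals = np.clip(rng.uniform(0.01, 0.99, size=(n, s)), 1e-3, 1 - 1e-3)
    return decoding.ReactivationMatrix(values=vals, rate=rate)
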