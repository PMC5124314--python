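import numpy as np
import pytest

import lbsizecleav as lb


@pytest.fixture(scope="session")
def small_planted_dataset():
    """60 hairpins with the loop-length cue always planted (seeded)."""
    params = lb.SyntheticParams(n_precursors=60, signal_strength=1.0)
    precursors, truth = lb.generate_dataset(params, seed=123)
    return params, precursors, truth


@pytest.fixture(scope="session")
def small_null_dataset():
    """100 hairpins with no planted cue: windows are label-independent."""
    params = lb.SyntheticParams(n_precursors=100, signal_strength=0.0)
    precursors, truth = lb.generate_dataset(params, seed=321)
    return params, precursors, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
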