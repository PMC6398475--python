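import numpy as np
import pytest

from ebtip import simgen


@pytest.fixture
def small_noise_free_stack():
    """Tiny deterministic stack: fully labelled, no sampling or noise."""
    cfg = simgen.SimImageConfig(seed=0, noise_free=True, labeled_fraction=1.0,
                                n_frames=4)
    return simgen.simulate_microtubule_stack(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
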