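import numpy as np
import pytest
from hypothesis import settings

import wingtrap as wt
from wingtrap import rules

settings.register_profile("default", derandomize=True, max_examples=25)
settings.load_profile("default")


@pytest.fixture(scope="session")
def oleae_preset():
    return wt.make_preset("B. oleae")


@pytest.fixture(scope="session")
def oleae_thresholds(oleae_preset):
    """Rule thresholds calibrated on 200 synthetic positives (seed 11)."""
    rng = np.random.default_rng(11)
    positives = [wt.synth_snippet(oleae_preset, rng=rng) for _ in range(200)]
    return rules.calibrate(positives)


def make_snippets(species, n, seed):
    rng = np.random.default_rng(seed)
    preset = wt.make_preset(species)
    return [wt.synth_snippet(preset, rng=rng) for _ in range(n)]
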