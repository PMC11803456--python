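from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

from hgamap import (ParadigmSpec, SyntheticConfig, extract_trial_samples,
                    generate_recording, preprocess)

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_spec():
    return ParadigmSpec()


@pytest.fixture(scope="session")
def default_session(default_spec):
    """One fully processed synthetic session: 16 channels, 8 responsive."""
    cfg = SyntheticConfig(seed=42)
    rec, timeline, truth = generate_recording(cfg, default_spec)
    z = preprocess(rec, timeline)
    trials = extract_trial_samples(z, timeline)
    return SimpleNamespace(cfg=cfg, rec=rec, timeline=timeline, truth=truth,
                           z=z, trials=trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
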