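import numpy as np
import pandas as pd
import pytest

from driftband import synth


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-effects study shared across read-only tests."""
    return synth.generate_dataset(n_subjects=8, bin_targets=(2, 2, 2, 2),
                                  n_trials_per_condition=24, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def toy_trials():
    """Four-trial table with three correct answers."""
    return pd.DataFrame({
        "subject": ["s0"] * 4,
        "condition": [1, 1, 2, 2],
        "coherence": [0.025, 0.025, 0.05, 0.05],
        "direction": [1, -1, 1, -1],
        "choice": [1, -1, 1, 1],
        "rt_s": [0.6, 0.7, 0.8, 0.9],
        "confidence": [2, 2, 3, 1],
    })
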