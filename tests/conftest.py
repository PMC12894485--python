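import numpy as np
import pytest

from mscsf.simulate import SimConfig


def brute_force_auc(scores, labels):
    """Independent AUROC oracle: explicit pair counting with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture
def small_config():
    """A fast cohort configuration for structural tests."""
    return SimConfig(n_rrms=20, n_progms=10, n_oind=8, n_nind=8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
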