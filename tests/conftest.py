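"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from eegsplit import GeneratorConfig, build_dataset, iter_cohort


@pytest.fixture(scope="session")
def small_features():
    """Feature matrix for a 6+6 subject cohort (40 s recordings).

    Default generator amplitudes apply: MDD alpha doubled, theta raised —
    the classes are separable by design.
    """
    cfg = GeneratorConfig(n_healthy=6, n_mdd=6, duration_s=40.0, seed=11)
    return build_dataset(iter_cohort(cfg))


@pytest.fixture(scope="session")
def separable_cloud():
    """Two well-separated Gaussian clouds in 5 dimensions."""
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 0.3, size=(40, 5))
    b = rng.normal(4.0, 0.3, size=(40, 5))
    X = np.vstack([a, b])
    y = np.r_[np.zeros(40, dtype=int), np.ones(40, dtype=int)]
    return X, y
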