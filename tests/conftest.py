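import numpy as np
import pytest

from emodyn.decomposition import ACCUMULATION, EXPLOSIVENESS
from emodyn.synth import PlantedROI, SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_cfg():
    """A small, fast synthetic-study configuration for unit tests."""
    return SynthConfig(
        n_participants=4,
        grid_shape=(16, 16, 12),
        planted_rois=(
            PlantedROI((4, 4, 6), 2.0, EXPLOSIVENESS, 0.5),
            PlantedROI((11, 11, 6), 2.0, ACCUMULATION, 0.5),
        ),
    )


@pytest.fixture
def small_profile_matrix():
    """Noiseless rank-2 profile matrix with known loadings and scores.

    Includes a few pure single-component trials (score 0 on the other
    component — profiles that return fully to baseline, or build from
    nothing), which makes the exact nonnegative factorisation unique so the
    generating loadings are a valid recovery oracle.
    """
    from emodyn.synth import (default_accumulation_loading,
                              default_explosiveness_loading)
    rng = np.random.default_rng(7)
    h_e = default_explosiveness_loading()
    h_a = default_accumulation_loading()
    s = rng.lognormal(mean=np.log(500), sigma=1.0, size=(60, 2))
    s[:3, 1] = 0.0   # pure-explosiveness trials
    s[3:6, 0] = 0.0  # pure-accumulation trials
    X = np.outer(s[:, 0], h_e) + np.outer(s[:, 1], h_a)
    return X, s, h_e, h_a
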