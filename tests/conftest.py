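import numpy as np
import pytest

import wheatfusion as wf
from wheatfusion import enr


@pytest.fixture(scope="session")
def trial():
    """Default-calibration 180-plot trial (6 stages)."""
    return wf.simulate_trial(seed=11)


@pytest.fixture(scope="session")
def noiseless_trial():
    """180-plot trial with every canopy noise knob at zero."""
    return wf.simulate_trial(seed=11, link_params=wf.CanopyLinkParams().noiseless())


@pytest.fixture(scope="session")
def small_trial():
    """60-plot trial (10 genotypes x 3 treatments x 2 replicates)."""
    return wf.simulate_trial(10, 3, 2, seed=7)


@pytest.fixture(scope="session")
def gf_table(trial):
    return wf.build_feature_table(trial, "grain_filling")


@pytest.fixture(scope="session")
def small_table(small_trial):
    return wf.build_feature_table(small_trial, "heading")


@pytest.fixture
def tiny_grid():
    """Four candidates spanning no-shrinkage to moderate shrinkage."""
    return enr.HyperGrid((0.0, 0.5), (0.5, 1.0), "cartesian")


@pytest.fixture
def fast_cv():
    return enr.CVConfig(outer_folds=5, outer_repeats=1, inner_folds=4, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
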