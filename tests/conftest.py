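"""Shared fixtures: phantom studies are generated once per session."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from strokeperf.model import DscPerfusion
from strokeperf.phantom import default_spec, make_study, multilevel_spec


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default two-compartment phantom (healthy + delayed lesion), no noise."""
    return make_study(default_spec(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_results(noiseless_phantom):
    study, _ = noiseless_phantom
    return DscPerfusion(study).fit()


@pytest.fixture(scope="session")
def multilevel_phantom():
    """Graded-flow phantom spanning CBF 20..60, no noise."""
    return make_study(multilevel_spec(seed=2))


@pytest.fixture(scope="session")
def multilevel_results(multilevel_phantom):
    study, _ = multilevel_phantom
    return DscPerfusion(study).fit()


@pytest.fixture()
def small_study():
    """Tiny synthetic study for I/O and preprocessing unit tests."""
    rng = np.random.default_rng(0)
    from strokeperf.io import PerfusionStudy

    signal = rng.uniform(50.0, 100.0, (16, 16, 4, 24))
    return PerfusionStudy(signal=signal, tr_s=1.5, te_s=0.04, voxel_mm=(1.0, 1.0, 5.0))
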