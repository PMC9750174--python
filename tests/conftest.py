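import numpy as np
import pytest

from indentmap.grid import default_grid
from indentmap.simulate import GroundTruth, StudyConfig, make_study


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def noiseless_truth():
    return GroundTruth(force_noise=0.0, sample_noise=0.0, baseline_noise_N=0.0,
                       probe_noise_um=0.0, atypical_rate=0.0, np_failure_rate=0.0)


@pytest.fixture(scope="session")
def small_study():
    """A small default-noise two-genotype study shared across tests."""
    return make_study(StudyConfig(n_control=3, n_knockout=2, seed=11))


@pytest.fixture(scope="session")
def small_results(small_study):
    from indentmap.study import IndentationStudy

    return IndentationStudy.from_simulation(small_study).fit()
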