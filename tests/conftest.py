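import numpy as np
import pytest

from lagmine.io import PipelineConfig
from lagmine.preprocess import align_timepoints
from lagmine.synthetic import gen_synthetic_study, write_study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_study():
    """A compact planted-driver study shared across tests."""
    return gen_synthetic_study(G=30, T=9, R=2, n_drivers=1, lag=1, seed=7)


@pytest.fixture(scope="session")
def small_aligned(small_study):
    return align_timepoints(small_study.expression, small_study.metabolites, True)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, small_study):
    d = tmp_path_factory.mktemp("study")
    write_study(small_study, d)
    return d


@pytest.fixture
def default_cfg():
    return PipelineConfig(target_metabolite="met_target", method="ccm", max_lag=1)
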