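import warnings

import numpy as np
import pytest

import gppattrib as ga

warnings.filterwarnings("ignore", message="period not a multiple")


def make_flux(values, grid=None, year_start=1901, model_id="M",
              experiment_id="SG3"):
    """Wrap a (time, lat, lon) array into a FluxField on a small grid."""
    if grid is None:
        grid = ga.GridSpec.regular(values.shape[1], values.shape[2])
    da = ga.make_data_array(np.asarray(values, dtype=float), grid, year_start)
    return ga.FluxField(da, model_id=model_id, experiment_id=experiment_id)


@pytest.fixture(scope="session")
def small_config():
    """Reduced synthetic world used by most unit tests."""
    return ga.TruthConfig(n_lat=8, n_lon=12, n_years=40, block_years=20,
                          n_models=5, n_nitrogen_models=2, seed=7)


@pytest.fixture(scope="session")
def small_archive(small_config):
    return ga.generate_factorial_ensemble(small_config)


@pytest.fixture(scope="session")
def small_coupled(small_config):
    return ga.generate_coupled_analog(small_config)


@pytest.fixture(scope="session")
def default_archive():
    """Full-size default synthetic world (11 models, 110 years, global
    24x48 grid); shared across the slower end-to-end checks."""
    return ga.generate_factorial_ensemble(ga.TruthConfig())
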