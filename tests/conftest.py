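"""Shared fixtures: small seeded synthetic scenes used across test modules."""

import numpy as np
import pytest

import siderocell as sc


@pytest.fixture(scope="session")
def double_reporter():
    return sc.StrainSpec("double_reporter", {"mcherry": "pvdA", "egfp": "pchEF"})


@pytest.fixture(scope="session")
def wildtype():
    return sc.StrainSpec("PAO1_wt")


@pytest.fixture(scope="session")
def noiseless_optics():
    return sc.OpticsParams(image_shape_px=(256, 256),
                           pad_background_sd=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_field(double_reporter, noiseless_optics):
    """12 well-separated cells rendered at zero camera noise."""
    pop = sc.PopulationParams(n_cells_per_field=12)
    cells = sc.sample_population(pop, 6.0, double_reporter, rng=11,
                                 image_shape=noiseless_optics.image_shape_px)
    img = sc.render_field(cells, noiseless_optics, rng=12)
    return cells, img, noiseless_optics


@pytest.fixture(scope="session")
def mini_experiment_config():
    """1 condition × 3 time points × 2 strains × 2 repeats; fast to render."""
    return sc.ExperimentConfig(
        conditions=("bipyridyl_100",),
        repeats=2,
        n_cell_fields=1,
        n_blank_fields=4,
        population=sc.PopulationParams(n_cells_per_field=120,
                                       time_points_h=(3.0, 9.0, 24.0)),
        optics=sc.OpticsParams(image_shape_px=(400, 400)),
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_pipeline_result(mini_experiment_config):
    return sc.run_pipeline(mini_experiment_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
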