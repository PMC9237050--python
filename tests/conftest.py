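import numpy as np
import pytest

from neurocrit import (
    HealthyCalibration,
    ModelParams,
    generate_healthy_connectome,
    generate_parcellation,
    homeostatic_normalize,
    threshold_connectome,
)


@pytest.fixture(scope="session")
def parc40():
    return generate_parcellation(n_nodes=40, n_networks=4, seed=7)


@pytest.fixture(scope="session")
def small_calibration():
    # scaled-down generator for 40-node test graphs
    return HealthyCalibration(
        strong_degree=8.0, medium_degree=1.0, weak_degree=3.0,
        distance_scale=60.0, strong_mean=60.0, strong_sd=6.0,
    )


@pytest.fixture(scope="session")
def healthy40(parc40, small_calibration):
    return generate_healthy_connectome(parc40, small_calibration, seed=11)


@pytest.fixture(scope="session")
def norm40(healthy40):
    return homeostatic_normalize(threshold_connectome(healthy40))


@pytest.fixture(scope="session")
def fast_params():
    # coarse grid / short run for unit tests of the sweep machinery
    return ModelParams(
        T_grid=np.round(np.arange(0.0, 0.201, 0.01), 6),
        t_s=400, burn_in=50, n_reps=2, seed=3,
    )
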