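import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import spdesdm as s


@pytest.fixture(scope="session")
def small_mesh():
    """~250-vertex mesh on a 30x30 km domain with the default-style buffer."""
    return s.build_mesh(box(0, 0, 30, 30), 3.0, buffer=8.0)


@pytest.fixture(scope="session")
def small_spde(small_mesh):
    return s.SPDEModel.from_mesh(small_mesh, 10.0, 1.0)


@pytest.fixture(scope="session")
def logistic_data():
    """Fixed synthetic logistic data: n=2000, 3 covariates, no field."""
    rng = np.random.default_rng(3)
    n = 2000
    raw = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
    dm = s.scale_covariates(raw)
    from scipy.special import expit

    eta = -0.3 + dm.values.to_numpy() @ np.array([-1.0, 0.8, -0.5])
    z = (rng.random(n) < expit(eta)).astype(int)
    return dm, z


@pytest.fixture(scope="session")
def tiny_stack():
    """30x30 km synthetic covariate stack, fixed seed."""
    return s.simulate_covariates(s.LandscapeConfig(extent_km=30.0, seed=5))
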