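import numpy as np
import pytest

import replearn as rl


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240123)


@pytest.fixture(scope="session")
def small_regression():
    """Sparse linear data small enough for fast end-to-end runs."""
    return rl.simulate_regression(n_obs=80, n_features=10, n_informative=3,
                                  coefficient_scale=2.0, noise_sd=0.5, seed=11)


@pytest.fixture(scope="session")
def small_classification():
    return rl.simulate_classification(n_obs=100, n_features=20, n_informative=3,
                                      effect_size=2.0, seed=11)


@pytest.fixture(scope="session")
def tiny_evaluation(small_regression):
    """A 2-size x 3-repeat lasso evaluation reused across report/importance tests."""
    ds, _ = small_regression
    spec = rl.LearnerSpec("glm_penalized", "regression",
                          {"alpha": [0.01, 0.1], "l1_ratio": [1.0]})
    grid = rl.SizeGrid(sizes=(40, 60), n_repeats=3)
    return ds, rl.evaluate_method(ds, spec, grid, "mse", seed=5)
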