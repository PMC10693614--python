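import numpy as np
import pytest

import dronesurvey as ds


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_counts():
    cd, truth = ds.generate_counts(19.0, 0.55, 8, 4, seed=101)
    return cd, truth


@pytest.fixture(scope="session")
def noiseless_zoo():
    return ds.generate_growth(n=23, noise_cv=0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_zoo():
    return ds.generate_growth(n=23, noise_cv=0.08, seed=7)
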