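import numpy as np
import pytest

import growthcompare as gc

STUDY_AGES = np.array(gc.OBSERVATION_AGES, dtype=float)


@pytest.fixture(scope="session")
def ages():
    return STUDY_AGES.copy()


@pytest.fixture(scope="session")
def gompertz_danish():
    return gc.preset_params("danish", "gompertz")


@pytest.fixture(scope="session")
def gompertz_french():
    return gc.preset_params("french", "gompertz")


@pytest.fixture(scope="session")
def noiseless_gompertz_dataset(gompertz_danish):
    """Eight-point noiseless trajectory from the Danish Gompertz preset."""
    w = gc.evaluate("gompertz", gompertz_danish, STUDY_AGES)
    return gc.GrowthDataset("danish", STUDY_AGES, np.asarray(w))


@pytest.fixture()
def fast_fit_config():
    """Few restarts: plenty for clean data, keeps Monte-Carlo loops quick."""
    return gc.FitConfig(restarts=4, seed=7)
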