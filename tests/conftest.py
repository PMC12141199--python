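import warnings

import numpy as np
import pytest

import mssf
from mssf.config import RunConfig


@pytest.fixture(scope="session")
def worked():
    """The hand-enumerable 4-drug x 3-side-effect instance."""
    return mssf.worked_example()


@pytest.fixture(scope="session")
def worked_bank(worked):
    dsa, raw = worked
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero target profile is intentional
        return mssf.build_bank(dsa, raw)


@pytest.fixture(scope="session")
def small_fixture():
    """A 20x24 planted-signal dataset with its full similarity bank."""
    spec = mssf.FixtureSpec(n_drugs=20, n_side_effects=24, seed=7)
    dsa, raw = mssf.generate(spec)
    return dsa, raw, mssf.build_bank(dsa, raw)


@pytest.fixture()
def tiny_config():
    """Config sized so a training run takes about a second."""
    return RunConfig.desk_scale(epochs=3, patience=2, batch_size=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
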