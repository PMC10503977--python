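import numpy as np
import pytest

from qsarkit import fit
from qsarkit.fixtures import load_descriptor_table


@pytest.fixture(scope="session")
def chalcones():
    """The packaged 25-compound chalcone dataset (20 train / 5 test)."""
    return load_descriptor_table()


@pytest.fixture(scope="session")
def chalcones_frame():
    """Raw fixture frame including the printed fitted/LOO predictions."""
    _, frame = load_descriptor_table(with_predictions=True)
    return frame


@pytest.fixture(scope="session")
def chalcone_model(chalcones):
    """OLS model refitted on the 20 training compounds."""
    return fit(chalcones)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
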