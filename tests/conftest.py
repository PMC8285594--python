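import numpy as np
import pytest

from spherelimits.synthetic_data import default_protocol, lte_pgse_protocol
from spherelimits.waveforms import make_lte_pgse

DELTA, BIG_DELTA = 29.65, 37.05


@pytest.fixture(scope="session")
def protocol():
    """The full 18-shell LTE/PTE/STE protocol (shared; building the shell
    spectra caches is the expensive part)."""
    return default_protocol()


@pytest.fixture(scope="session")
def pgse_protocol():
    """High-b LTE-only pulsed protocol used by the power-law experiments."""
    return lte_pgse_protocol((6.0, 7.5, 9.0, 10.5))


@pytest.fixture()
def pgse():
    return make_lte_pgse(DELTA, BIG_DELTA, amplitude=60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Haar-ish random rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
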