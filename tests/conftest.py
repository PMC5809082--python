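import numpy as np
import pytest

from cmscortex.dmri_data import study_protocol


@pytest.fixture(scope="session")
def protocol():
    """The study's 14-shell × 12-direction ex-vivo protocol."""
    return study_protocol()


@pytest.fixture(scope="session")
def meas(protocol):
    """Expanded per-measurement (bvals, bvecs)."""
    return protocol.expand()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_spd(rng, scale=1.0, floor=0.1):
    a = rng.standard_normal((3, 3))
    return scale * (a @ a.T / 3.0 + floor * np.eye(3))


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
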