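import numpy as np
import pytest

from zknock import LDMatrix, psd_repair


@pytest.fixture
def sigma_identity():
    return psd_repair(np.eye(3))


@pytest.fixture
def sigma_08():
    """2x2 equicorrelated LD with r = 0.8."""
    return psd_repair(np.array([[1.0, 0.8], [0.8, 1.0]]))


@pytest.fixture
def sigma_05():
    """2x2 equicorrelated LD with r = 0.5."""
    return psd_repair(np.array([[1.0, 0.5], [0.5, 1.0]]))


@pytest.fixture
def sigma_ar1():
    """20-variant AR(1) LD with rho = 0.5."""
    idx = np.arange(20)
    R = 0.5 ** np.abs(idx[:, None] - idx[None, :])
    return psd_repair(R)


def random_psd_corr(p: int, rng: np.random.Generator) -> LDMatrix:
    """Random well-conditioned correlation matrix."""
    A = rng.standard_normal((p, 2 * p))
    R = np.corrcoef(A)
    return psd_repair(0.9 * R + 0.1 * np.eye(p))
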