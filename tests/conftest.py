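import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from subspaceboost import Dataset, center, preset_setting, simulate_replicate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_dataset(rng):
    """Well-conditioned 30 x 6 regression problem with 2 signal variables."""
    X = rng.standard_normal((30, 6))
    y = 1.5 * X[:, 0] - 2.0 * X[:, 2] + 0.5 * rng.standard_normal(30)
    return center(Dataset(X=X, y=y))


@pytest.fixture()
def lowdim_replicate():
    return simulate_replicate(preset_setting("lowdim", seed=42, test_n=200))


@pytest.fixture()
def orthonormal_dataset(rng):
    """Dataset whose centered columns are exactly orthonormal."""
    A = rng.standard_normal((40, 8))
    A = A - A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    Q = Q - Q.mean(axis=0)  # QR of centered data is already centered
    y = Q @ np.array([3.0, -2.0, 1.0, 0.5, 0.0, 0.0, 0.0, 0.0])
    y += 0.01 * rng.standard_normal(40)
    return center(Dataset(X=Q, y=y))
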