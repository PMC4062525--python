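import numpy as np
import pytest
import scipy.linalg
from hypothesis import HealthCheck, settings

from cssbn import build_p53_network, generate_random_network

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def p53():
    """The two-gene p53-Mdm2 PBN at its reference operating point."""
    return build_p53_network(p=0.01, q=0.9)


@pytest.fixture(scope="session")
def random_models():
    """A spread of small random PBNs for property checks."""
    return [
        generate_random_network(n=n, max_functions=mf, seed=seed)
        for n, mf, seed in [(2, 2, 1), (2, 3, 2), (3, 2, 3), (3, 2, 4), (4, 2, 5)]
    ]


def stationary_eig(matrix: np.ndarray) -> np.ndarray:
    """Independent stationary-distribution oracle: left principal eigenvector."""
    w, vl = scipy.linalg.eig(matrix, left=True, right=False)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.real(vl[:, i])
    return pi / pi.sum()


@pytest.fixture(scope="session")
def eig_oracle():
    return stationary_eig
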