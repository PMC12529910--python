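import numpy as np
import pytest

from rtbse import make_random_bundle, make_two_level


@pytest.fixture(scope="session")
def two_level_ip():
    """Independent-particle two-level system, 6 eV gap, unit dipole."""
    return make_two_level(6.0, 1.0, "none")


@pytest.fixture(scope="session")
def two_level_bare():
    """Two-level system with bare interaction (W = V)."""
    return make_two_level(6.0, 1.0, "bare")


@pytest.fixture(scope="session")
def random_bundle():
    """Small interacting bundle with a nonorthogonal basis."""
    return make_random_bundle(n_ao=4, n_occ=1, n_aux=8, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_hermitian(rng, n):
    a = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    return 0.5 * (a + a.conj().T)


def random_spd(rng, n, shift=0.5):
    a = rng.normal(size=(n, n))
    return a @ a.T / n + shift * np.eye(n)
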