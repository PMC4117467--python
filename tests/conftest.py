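import numpy as np
import pytest

from fiberlift.sphere import build_angular_operators, tessellate_icosphere


@pytest.fixture(scope="session")
def tess0():
    return tessellate_icosphere(0)


@pytest.fixture(scope="session")
def tess1():
    return tessellate_icosphere(1)


@pytest.fixture(scope="session")
def tess2():
    return tessellate_icosphere(2)


@pytest.fixture(scope="session")
def tess3():
    return tessellate_icosphere(3)


@pytest.fixture(scope="session")
def ops1(tess1):
    return build_angular_operators(tess1)


@pytest.fixture(scope="session")
def ops2(tess2):
    return build_angular_operators(tess2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


def random_spd_tensors(n: int, seed: int, lo: float = 1e-4, hi: float = 3e-3) -> np.ndarray:
    """Seeded random SPD tensors: log-uniform eigenvalues in [lo, hi] mm^2/s,
    uniformly random rotations."""
    gen = np.random.default_rng(seed)
    lam = 10 ** gen.uniform(np.log10(lo), np.log10(hi), size=(n, 3))
    # random rotations via QR of Gaussian matrices (Haar-ish, fully seeded)
    A = gen.standard_normal((n, 3, 3))
    Q, R = np.linalg.qr(A)
    sign = np.sign(np.einsum("nii->ni", R))
    Q = Q * sign[:, None, :]
    return np.einsum("nij,nj,nkj->nik", Q, lam, Q)
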