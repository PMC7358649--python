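import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def parratt_reflectivity(stack, q):
    """Independent oracle: Parratt recursion with Nevot-Croce roughness.

    Algebraically equivalent to the transfer-matrix method but computed
    bottom-up through a different recurrence; used to cross-check the
    Abelès kernel.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    d = np.array([s.thickness for s in stack])
    rho = np.array([s.sld for s in stack])
    sigma = np.array([s.roughness for s in stack])
    n = len(stack)
    k = np.sqrt((q[:, None] / 2.0) ** 2 - 4.0 * np.pi * (rho[None, :] - rho[0]) + 0j)
    r = np.zeros_like(q, dtype=complex)
    for j in range(n - 2, -1, -1):
        kj, kj1 = k[:, j], k[:, j + 1]
        rj = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * sigma[j + 1] ** 2)
        if j == n - 2:
            r = rj
        else:
            phase = np.exp(2j * kj1 * d[j + 1])
            r = (rj + r * phase) / (1.0 + rj * r * phase)
    return np.minimum(np.abs(r) ** 2, 1.0)


@pytest.fixture(scope="session")
def q_grid():
    return np.linspace(0.005, 0.5, 400)


@pytest.fixture(scope="session")
def study_fixture_oriented():
    """Seeded study fixture generated under the N-in oriented scenario."""
    import nrdecomp as nd

    return nd.generate_study_fixture(20260901, scenario="oriented_n_in")


def random_stack(rng, n_layers):
    """A random physically plausible slab stack with n_layers internal layers."""
    from nrdecomp import Slab

    slabs = [Slab(0.0, rng.uniform(-1e-6, 4e-6))]
    for _ in range(n_layers):
        slabs.append(
            Slab(rng.uniform(5.0, 200.0), rng.uniform(-2e-6, 9e-6), rng.uniform(0.0, 5.0))
        )
    slabs.append(Slab(0.0, rng.uniform(-1e-6, 7e-6), rng.uniform(0.0, 5.0)))
    return slabs
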