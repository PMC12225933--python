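import numpy as np
import pytest

from dermafold import mechanics as mech
from dermafold import synthetic as syn


@pytest.fixture(scope="session")
def small_cap():
    """A reduced-width layered cap, cheap enough for repeated simulations."""
    return syn.make_layered_cap(half_width_fraction=0.04, seed=7)


@pytest.fixture(scope="session")
def unit_cube_mesh():
    return syn.make_uniform_block(1.0, 1.0, 1.0, spacing=1.0)


@pytest.fixture(scope="session")
def random_tet_batch():
    """100 well-conditioned random tetrahedra with random deformations."""
    rng = np.random.default_rng(42)
    batch = []
    while len(batch) < 100:
        X = rng.normal(size=(4, 3))
        vol = np.linalg.det((X[1:] - X[0]).T) / 6.0
        if vol < 0:
            X[[2, 3]] = X[[3, 2]]
            vol = -vol
        if vol < 0.05:          # skip slivers: FD oracle conditioning
            continue
        x = X + 0.1 * rng.normal(size=(4, 3))
        g_t, g_n = rng.uniform(-0.2, 0.6, size=2)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        G = mech.growth_tensor(n, g_t, g_n)
        Fe = ((x[1:] - x[0]).T
              @ np.linalg.inv((X[1:] - X[0]).T) @ np.linalg.inv(G))
        if np.linalg.det(Fe) < 0.2:      # keep clear of inversion for FD
            continue
        mu, lam = mech.lame_parameters(rng.uniform(0.5, 3.0),
                                       rng.uniform(0.0, 0.45))
        batch.append((X, x, n, g_t, g_n, mu, lam))
    return batch
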