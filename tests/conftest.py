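import numpy as np
import pytest

from sasamc.cg_model import build_caffeine_template
from sasamc.sasa_potential import PairTable


@pytest.fixture(scope="session")
def caffeine():
    return build_caffeine_template()


@pytest.fixture(scope="session")
def caffeine_table(caffeine):
    return PairTable(caffeine)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def mc_sphere_area_oracle(centers, radii, which, n_points, rng):
    """Monte-Carlo surface-point oracle: exposed area of sphere ``which``
    against all other spheres (uniform surface sampling)."""
    c0 = centers[which]
    R0 = radii[which]
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts = c0 + R0 * pts
    outside = np.ones(n_points, dtype=bool)
    for j, (cj, Rj) in enumerate(zip(centers, radii)):
        if j == which:
            continue
        outside &= np.einsum("ij,ij->i", pts - cj, pts - cj) > Rj**2
    return 4.0 * np.pi * R0**2 * outside.mean()


def two_sphere_area_oracle(R, r, d, n_points, rng):
    centers = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    radii = np.array([R, r])
    return (mc_sphere_area_oracle(centers, radii, 0, n_points, rng)
            + mc_sphere_area_oracle(centers, radii, 1, n_points, rng))
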