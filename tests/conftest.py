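import numpy as np
import pytest

from supfield import Population, SFMParams


@pytest.fixture
def two_type_pop():
    """Equal mixture of a strong and a weak suppressor."""
    return Population([0.5, 0.5], [0.8, 0.2], 0.8, [0.5, 0.5])


@pytest.fixture
def grid_pop():
    """Canonical 13 x 13 trait grid (169 genotypes, equal densities)."""
    return Population.trait_grid(13)


@pytest.fixture
def rng():
    return np.random.default_rng(20230222)


def random_population(rng, k=10):
    """Random in-range population on the canonical trait domain."""
    d = rng.dirichlet(np.full(k, 2.0))
    return Population(
        rng.uniform(0.2, 0.8, k),
        rng.uniform(0.2, 0.8, k),
        rng.uniform(0.5, 0.95, k),
        d,
    )


def random_params(rng, **kw):
    base = dict(
        alpha=rng.uniform(0.3, 1.0),
        rho=rng.uniform(0.3, 1.0),
        beta=rng.uniform(0.0, 1.0),
        n=int(rng.integers(1, 12)),
        phi=float(rng.choice([0.5, 1.0, 2.0, 10.0, 100.0])),
    )
    base.update(kw)
    return SFMParams(**base)
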