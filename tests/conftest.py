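import numpy as np
import pytest

from phylohypo import phylolik as pl
from phylohypo import synthgen as sg


@pytest.fixture(scope="session")
def lg():
    return pl.lg_model()


@pytest.fixture(scope="session")
def lg_gamma_inv():
    return pl.lg_model(gamma_shape=0.8, n_categories=4, p_invariant=0.2)


def random_model(rng: np.random.Generator, gamma: bool = False,
                 invariant: bool = False) -> pl.SubstitutionModel:
    """A random valid reversible amino-acid model (for oracle checks)."""
    s = rng.uniform(0.05, 2.0, size=(20, 20))
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 0.0)
    pi = rng.dirichlet(np.full(20, 5.0))
    return pl.SubstitutionModel(
        exchangeabilities=s,
        frequencies=pi,
        gamma_shape=float(rng.uniform(0.3, 2.0)) if gamma else None,
        n_categories=4,
        p_invariant=float(rng.uniform(0.05, 0.4)) if invariant else 0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def yule_tree_factory():
    def make(n_taxa, seed, birth_rate=1.0):
        return sg.simulate_yule_tree(n_taxa, birth_rate, seed)

    return make
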