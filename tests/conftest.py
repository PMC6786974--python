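"""Shared fixtures: small synthetic cohorts and a cached structured kinship.

The heavier objects (the N=2000 genotype-derived kinship and its
eigendecomposition) are session-scoped because several mixed-model tests and
the acceptance checks reuse them.
"""

import numpy as np
import pytest

import mtgwas as m
from mtgwas.mixedmodel import KinshipMatrix, compute_rrm
from mtgwas.simdata import psd_sqrt


@pytest.fixture(scope="session")
def small_genotypes():
    return m.simulate_genotypes(200, 100, seed=11)


@pytest.fixture(scope="session")
def small_covariates():
    return m.simulate_covariates(200, seed=12)


@pytest.fixture(scope="session")
def rrm_2000():
    """Genotype-derived RRM kinship for N=2000: the eigenvalue spread of a
    finite-marker RRM is what identifies genetic vs residual covariance."""
    G = m.simulate_genotypes(2000, 500, seed=42, ld_decay=np.inf)
    K = compute_rrm(G)
    K.eigendecomposition()  # cache once for the whole session
    return K


@pytest.fixture(scope="session")
def kinship_sqrt_2000(rrm_2000):
    return psd_sqrt(rrm_2000.values)


def sample_matrix_normal(LK, B, E, n, p, rng):
    """Direct matrix-normal draw Y = L_K Z L_B' + Z' L_E' used as the
    independent sampler in recovery tests."""
    return (LK @ rng.standard_normal((n, p)) @ psd_sqrt(B).T
            + rng.standard_normal((n, p)) @ psd_sqrt(E).T)


@pytest.fixture(scope="session")
def identity_kinship_200():
    return KinshipMatrix(values=np.eye(200), samples=[f"S{i:05d}" for i in range(200)],
                         source="identity")
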