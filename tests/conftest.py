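from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import symptomnet as sn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_matrix() -> sn.ResponseMatrix:
    """One realisation of the 22-node, four-community study stand-in."""
    return sn.generate(sn.default_study_spec(n=1463, seed=11))


@pytest.fixture(scope="session")
def study_ega(study_matrix) -> sn.EGAResult:
    return sn.ega(study_matrix, compute_layout=False)


def two_clique_network(
    n_per: int = 5, within: float = 0.5, bridge: float = 0.0
) -> sn.Network:
    """Two cliques of size n_per, optional single bridge edge."""
    p = 2 * n_per
    W = np.zeros((p, p))
    for a in range(n_per):
        for b in range(a + 1, n_per):
            W[a, b] = W[b, a] = within
            W[n_per + a, n_per + b] = W[n_per + b, n_per + a] = within
    if bridge:
        W[n_per - 1, n_per] = W[n_per, n_per - 1] = bridge
    return sn.Network(
        weights=W,
        precision=None,
        lambda_=0.0,
        node_codes=tuple(f"n{i}" for i in range(p)),
    )


@pytest.fixture
def random_pd_corr():
    def make(p: int, seed: int, n_rows: int | None = None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n_rows or 20 * p, p))
        return np.corrcoef(X, rowvar=False)

    return make
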