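"""Shared fixtures: small deterministic ensembles and parameter sets."""

import numpy as np
import pytest

from packetsim.core_model import (
    EnsembleState,
    GenerativeModelParams,
    softmax_beliefs,
)


@pytest.fixture
def raw_params():
    """Sensor model in its raw limit: no saturation, no floor, unit scale.

    This is the regime in which the closed-form flow equations hold
    verbatim (magnitude = weighted source distance, unbounded).
    """
    return GenerativeModelParams(
        D=1.0, prec_R=1.0, prec_psi=1.0, prec_mu=0.0,
        r_sat=float("inf"), intensity_floor=0.0, mu_max=float("inf"),
        noise_free=True,
    )


@pytest.fixture
def default_params():
    return GenerativeModelParams()


def make_ensemble(x, mu=None, a_psi=None, params=None, t=0):
    x = np.asarray(x, dtype=float)
    n = len(x)
    if mu is None:
        mu = np.zeros((n, 4))
    mu = np.asarray(mu, dtype=float)
    if a_psi is None:
        a_psi = softmax_beliefs(mu)
    if params is None:
        params = GenerativeModelParams()
    return EnsembleState(x=x, mu=mu, a_psi=np.asarray(a_psi, dtype=float),
                         t=t, params=params)


@pytest.fixture
def two_particle(raw_params):
    """Particle at origin plus a neighbour at offset (3, 4)."""
    return make_ensemble([[0.0, 0.0], [3.0, 4.0]], params=raw_params)


def random_ensemble(rng, n=8, box=4.0, params=None):
    x = rng.uniform(-box / 2, box / 2, size=(n, 2))
    mu = rng.normal(scale=1.0, size=(n, 4))
    return make_ensemble(x, mu=mu, params=params)
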