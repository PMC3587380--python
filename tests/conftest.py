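import numpy as np
import pytest

import diffvar as dv


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_posterior(p, rng):
    """A valid random PosteriorTheta for moment tests."""
    mu = rng.normal(scale=0.5, size=(p, p))
    prec = np.empty((p, p, p))
    for i in range(p):
        M = rng.normal(size=(p, p))
        prec[i] = M @ M.T + (p + 1) * np.eye(p)
    return dv.PosteriorTheta(
        mu_A=mu,
        prec_A=prec,
        u=rng.uniform(2.5, 6.0, p),
        k=rng.uniform(1.0, 4.0, p),
        v=rng.uniform(2.5, 6.0, p),
        l=rng.uniform(1.0, 4.0, p),
        zeta0=rng.uniform(1.0, 5.0, (p, p)),
        zeta1=rng.uniform(1.0, 5.0, (p, p)),
    )


def point_mass_posterior(A, h, r, zeta0=2.0, zeta1=2.0):
    """Posterior with (numerically) zero coefficient uncertainty.

    <1/h_i> is matched exactly through the IG mean; the coefficient
    covariance is forced to zero so moments reduce to plug-in values.
    """
    p = A.shape[0]
    big = 1e12
    theta = dv.PosteriorTheta(
        mu_A=np.asarray(A, float),
        prec_A=np.broadcast_to(big * np.eye(p), (p, p, p)).copy(),
        u=np.full(p, big),
        k=np.asarray(h, float) * big,
        v=np.full(p, big),
        l=np.asarray(r, float) * big,
        zeta0=np.full((p, p), zeta0),
        zeta1=np.full((p, p), zeta1),
        cov_A=np.zeros((p, p, p)),
    )
    return theta


def small_pair(seed=0, p=3, T=12, obs_sd=0.2, n_specific=1, coeffs=(-0.8, -0.6, 0.6, 0.8)):
    """Simulated two-condition dataset from a small stable network pair."""
    rng = np.random.default_rng(seed)
    E1 = np.eye(p, dtype=int)
    E2 = np.eye(p, dtype=int)
    for _ in range(n_specific):
        i, j = rng.choice(p, 2, replace=False)
        E1[i, j] = 1
    A = np.zeros((p, p))
    mask = (E1 + E2) > 0
    A[mask] = rng.choice(coeffs, size=int(mask.sum()))
    while max(
        np.abs(np.linalg.eigvals(A * E1)).max(),
        np.abs(np.linalg.eigvals(A * E2)).max(),
    ) >= 1:
        A[mask] = rng.choice(coeffs, size=int(mask.sum()))
    data = []
    for c, E in enumerate((E1, E2)):
        net = dv.NetworkModel(coeff=A * E, edges=E)
        data.append(
            dv.simulate_series(net, T, sys_sd=1.0, obs_sd=obs_sd, seed=rng, condition=c + 1)
        )
    nets = (dv.NetworkModel(coeff=A * E1, edges=E1), dv.NetworkModel(coeff=A * E2, edges=E2))
    return tuple(data), nets
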