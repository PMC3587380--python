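"""Variational E-step: smoothing of hidden trajectories under expected parameters.

Given the variational posteriors Q(Theta) and Q(E), the conditional
posterior over the hidden trajectory X of one condition,

    Q(X) ~ exp < log P(Y, X, Theta, E) >_{Q(Theta) Q(E)},

is a Gaussian Markov chain whose log density at grid step t collects

    -1/2 x_t' <H^-1> x_t + x_t' <H^-1 A o E> x_{t-1}
    -1/2 x_{t-1}' <(A o E)' H^-1 (A o E)> x_{t-1}

plus the observation quadratic at observed points. Because the quadratic
term uses the full expectation <(AoE)' H^-1 (AoE)> (not the outer product
of means), the chain is not a plain Kalman model; we therefore run the
smoother in information (precision) form on the exact block-tridiagonal
posterior precision, which handles skipped observations by simply leaving
out the measurement term. This computes the same moments a variational
Kalman filter/smoother would, and matches a dense joint-Gaussian solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg.lapack import dpotrf, dpotri, dpotrs

from .model import (
    EdgePosterior,
    LatentStats,
    ObservedSeries,
    PosteriorTheta,
    SmoothedMoments,
)

__all__ = ["ExpectedSystem", "expected_system", "smooth", "smooth_pair"]

logger = logging.getLogger(__name__)

_JITTER = 1e-9


@dataclass
class ExpectedSystem:
    """Expected system matrices for one condition under Q(Theta) Q(E).

    EA     = <A o E>                     (p, p)
    HinvAE = <H^-1 (A o E)>              (p, p)
    AEHAE  = <(A o E)' H^-1 (A o E)>     (p, p), symmetric PSD
    Hinv   = <H^-1> diagonal             (p,)
    Rinv   = <R^-1> diagonal             (p,)
    """

    EA: np.ndarray
    HinvAE: np.ndarray
    AEHAE: np.ndarray
    Hinv: np.ndarray
    Rinv: np.ndarray


def _second_moment_over_h(theta: PosteriorTheta) -> np.ndarray:
    """M2[i] = <A_i A_i' / h_i> = <1/h_i> mu_i mu_i' + inv(T_Ai).

    With Q(A_i | h_i) = N(mu_i, h_i inv(T_Ai)), the h_i factor of the
    conditional covariance cancels against the 1/h_i weight, leaving the
    h-free term inv(T_Ai).
    """
    hinv = theta.h_inv_mean()
    mu = theta.mu_A
    return hinv[:, None, None] * mu[:, :, None] * mu[:, None, :] + theta.cov_A


def expected_system(theta: PosteriorTheta, edges: EdgePosterior) -> list[ExpectedSystem]:
    """Moments of the masked system matrices for both conditions.

    Uses <A_ij E_ij> = e_ij mu_ij, independence of the E entries under the
    factorized Q(E), and <E_ij^2> = <E_ij> = e_ij on the diagonal of the
    quadratic term.
    """
    hinv = theta.h_inv_mean()
    rinv = theta.r_inv_mean()
    mu = theta.mu_A
    M2 = _second_moment_over_h(theta)
    out = []
    for c in range(2):
        e = edges.e[c]
        EA = e * mu
        HinvAE = hinv[:, None] * EA
        # <E_ij E_ik> = e_ij e_ik off the diagonal, e_ij on it
        EE = e[:, :, None] * e[:, None, :]
        diag = np.arange(e.shape[1])
        EE[:, diag, diag] = e
        AEHAE = np.einsum("ijk,ijk->jk", EE, M2)
        AEHAE = 0.5 * (AEHAE + AEHAE.T)
        out.append(ExpectedSystem(EA=EA, HinvAE=HinvAE, AEHAE=AEHAE, Hinv=hinv, Rinv=rinv))
    return out


def _chol(mat: np.ndarray, what: str) -> np.ndarray:
    """Lower Cholesky factor with a logged jitter fallback."""
    c, info = dpotrf(mat, lower=1, clean=0, overwrite_a=0)
    if info == 0:
        return c
    jitter = _JITTER * max(1.0, float(np.trace(mat)) / mat.shape[0])
    logger.warning("adding %.1e jitter to %s block before factorization", jitter, what)
    eye = np.eye(mat.shape[0])
    for _ in range(8):
        c, info = dpotrf(mat + jitter * eye, lower=1, clean=0, overwrite_a=0)
        if info == 0:
            return c
        jitter *= 10.0
    raise np.linalg.LinAlgError(f"{what} block not positive definite")


def smooth(series: ObservedSeries, sys: ExpectedSystem) -> SmoothedMoments:
    """Smoothed means, second moments and lag-one cross moments.

    Builds the block-tridiagonal posterior precision of the hidden
    trajectory and solves it exactly: a forward block elimination followed
    by a backward covariance recursion (the information-form equivalent of
    the Kalman filter + RTS smoother). Grid points without an observation
    contribute no measurement term (pure prediction).
    """
    grid = series.grid
    T = grid.n_grid
    p = series.n_genes
    P = sys.HinvAE
    PT = np.ascontiguousarray(P.T)
    Omega = sys.AEHAE
    obs_mask = grid.observed_mask()
    obs_col = {t: j for j, t in enumerate(grid.observed)}
    diag = np.diag_indices(p)

    # forward block elimination: U_t = D_t - P U_{t-1}^-1 P',
    # c_t = b_t + P U_{t-1}^-1 c_{t-1}
    gains = np.empty((T, p, p))   # G_t = U_t^-1 P'
    wvec = np.empty((T, p))       # w_t = U_t^-1 c_t
    chols = np.empty((T, p, p))
    logdet = 0.0
    rhs = np.empty((p, p + 1))
    rhs[:, :p] = PT
    for t in range(1, T + 1):
        D = Omega.copy() if t <= T - 1 else np.zeros((p, p))
        b = np.zeros(p)
        if t >= 2:
            D[diag] += sys.Hinv
        if obs_mask[t - 1]:
            D[diag] += sys.Rinv
            b += sys.Rinv * series.values[:, obs_col[t]]
        if t >= 2:
            D -= P @ gains[t - 2]
            b += P @ wvec[t - 2]
            D = 0.5 * (D + D.T)
        cf = _chol(D, f"precision (t={t})")
        logdet += 2.0 * float(np.log(np.diag(cf)).sum())
        rhs[:, p] = b
        sol, info = dpotrs(cf, rhs, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("backsolve failed in smoother")
        gains[t - 1] = sol[:, :p]
        wvec[t - 1] = sol[:, p]
        chols[t - 1] = cf

    # backward pass: means, marginal covariances, lag-one cross covariances
    mean = np.empty((p, T))
    second = np.empty((T, p, p))
    cross = np.empty((T - 1, p, p))
    iu = np.triu_indices(p, 1)

    def _inv_from_chol(cf: np.ndarray) -> np.ndarray:
        inv, info = dpotri(cf, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("inversion failed in smoother")
        inv[iu] = inv.T[iu]  # upper triangle holds stale input values
        return inv

    Sigma_next = _inv_from_chol(chols[-1])
    m_next = wvec[-1]
    mean[:, T - 1] = m_next
    second[T - 1] = Sigma_next + m_next[:, None] * m_next[None, :]
    for t in range(T - 1, 0, -1):
        Uinv = _inv_from_chol(chols[t - 1])
        G = gains[t - 1]                # smoother gain U_t^-1 P'
        m_t = wvec[t - 1] + G @ m_next
        Sigma_t = Uinv + G @ Sigma_next @ G.T
        Sigma_t = 0.5 * (Sigma_t + Sigma_t.T)
        cross_cov = Sigma_next @ G.T    # cov(x_{t+1}, x_t)
        mean[:, t - 1] = m_t
        second[t - 1] = Sigma_t + m_t[:, None] * m_t[None, :]
        cross[t - 1] = cross_cov + m_next[:, None] * m_t[None, :]
        Sigma_next = Sigma_t
        m_next = m_t

    if not np.all(np.isfinite(mean)) or not np.all(np.isfinite(second)):
        raise FloatingPointError("non-finite smoothed moments")
    return SmoothedMoments(mean=mean, second=second, cross=cross, logdet_precision=logdet)


def smooth_pair(
    data, theta: PosteriorTheta, edges: EdgePosterior
) -> tuple[LatentStats, list[ExpectedSystem]]:
    """Convenience wrapper: expected system + smoothing for both conditions."""
    systems = expected_system(theta, edges)
    stats = LatentStats(
        per_condition=(smooth(data[0], systems[0]), smooth(data[1], systems[1]))
    )
    return stats, systems
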