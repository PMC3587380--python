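"""Variational-annealing inference for the joint two-condition VAR-SSM.

The marginal likelihood over the binary edge indicators E is maximized by
tempered mean-field coordinate ascent on the lower bound

    L_tau = <log P(Y, X, Theta, E)> + H[Q(X)] + H[Q(Theta)] + tau H[Q(E)],

where Q factorizes as Q(X) Q(Theta) Q(E) with
Q(Theta) = prod_i Q(A_i | h_i) Q(h_i) Q(r_i) prod_j Q(z_ij) and
Q(E) = prod_{c,ij} Bernoulli(e_ij^(c)). Each cycle runs, in order, the
M-step (conjugate updates of Q(Theta)), empirical-Bayes hyperparameter
updates, the E-step (variational Kalman smoothing, :mod:`diffvar.kalman`),
and the tempered A-step (logistic updates of e_ij^(c) with gain 1/tau).
The temperature starts high (tau = 2.5), is divided by 1.05 after each
converged inner loop, and as tau -> 0 the Bernoulli posteriors harden into
the binary configuration that maximizes the marginal likelihood.

Setting tau = 1 throughout recovers the plain (non-annealed) variational
method, used here as the EM-style baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import betaln, digamma, expit, gammaln, polygamma

from .kalman import smooth_pair
from .model import (
    LOG2PI,
    AnnealSchedule,
    EdgePosterior,
    HyperParams,
    LatentStats,
    NetworkModel,
    ObservedSeries,
    PosteriorTheta,
    SmoothedMoments,
    TimeGrid,
)

__all__ = [
    "FitResult",
    "m_step",
    "a_step",
    "update_hyper_ig",
    "update_hyper_beta",
    "anneal_fit",
    "em_fit",
    "select_alpha0",
    "lower_bound",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12  # clipping for edge probabilities


@dataclass
class FitResult:
    """Outcome of a variational-annealing (or fixed-temperature) fit."""

    theta: PosteriorTheta
    edges: EdgePosterior
    stats: LatentStats
    hyper: HyperParams
    bound_trace: list            # [(tau, tempered bound)], tau-weighted E-entropy
    bound_trace_plain: list      # [(tau, bound with unweighted E-entropy)]
    networks: tuple[NetworkModel, NetworkModel]

    @property
    def n_cycles(self) -> int:
        return len(self.bound_trace)


# ---------------------------------------------------------------------------
# sufficient statistics


class _SuffStats:
    """Regression sufficient statistics pooled per condition from Q(X)."""

    def __init__(self, data, stats: LatentStats):
        self.Sxx = []      # sum_{t=1}^{T-1} <x_t x_t'>
        self.Gxy = []      # sum_{t=1}^{T-1} <x_{t+1} x_t'>
        self.s_diag = []   # sum_{t=2}^{T} diag<x_t x_t'>
        self.obs_sq = []   # sum_{t in obs} <(y_t - x_t)^2> per gene
        self.n_trans = []
        self.n_obs = []
        for c in range(2):
            sm: SmoothedMoments = stats[c]
            series: ObservedSeries = data[c]
            T = sm.n_steps
            self.Sxx.append(sm.second[: T - 1].sum(axis=0))
            self.Gxy.append(sm.cross.sum(axis=0))
            self.s_diag.append(
                np.einsum("tii->i", sm.second[1:])
            )
            obs_idx = np.asarray(series.grid.observed) - 1
            y = series.values
            m = sm.mean[:, obs_idx]
            s_ii = np.einsum("tii->ti", sm.second[obs_idx]).T
            self.obs_sq.append((y**2 - 2.0 * y * m + s_ii).sum(axis=1))
            self.n_trans.append(T - 1)
            self.n_obs.append(series.grid.n_observed)


# ---------------------------------------------------------------------------
# M-step


def m_step(
    stats: LatentStats,
    edges: EdgePosterior,
    hyper: HyperParams,
    data,
    suff: _SuffStats | None = None,
) -> PosteriorTheta:
    """Conjugate updates of Q(Theta) given Q(X) and Q(E).

    Row i of the coefficient matrix gets a Gaussian Q(A_i | h_i) =
    N(mu_i, h_i inv(T_i)) whose Gram matrix pools, over both conditions,
    the smoothed second moments masked by the edge probabilities
    (<E_ij E_ik> = e_ij e_ik off-diagonal, e_ij on it), plus the expected
    prior precision diag(f_ij/alpha1 + (1-f_ij)/alpha0). Q(h_i) and Q(r_i)
    are inverse-gamma with pooled system / observation residuals; Q(z_ij)
    is Beta with the expected disagreement of (E_ij^(1), E_ij^(2)) added
    to zeta_i0 and the expected agreement to zeta_i1.
    """
    ss = suff if suff is not None else _SuffStats(data, stats)
    p = edges.n_genes
    diag = np.arange(p)

    W = np.zeros((p, p, p))
    b = np.zeros((p, p))
    for c in range(2):
        e = edges.e[c]
        EE = e[:, :, None] * e[:, None, :]
        EE[:, diag, diag] = e
        W += EE * ss.Sxx[c][None, :, :]
        b += e * ss.Gxy[c]

    f = edges.f()
    prior_prec = f / hyper.alpha1 + (1.0 - f) / hyper.alpha0
    T_A = W
    T_A[:, diag, diag] += prior_prec
    T_A = 0.5 * (T_A + np.transpose(T_A, (0, 2, 1)))

    try:
        cov_A = np.linalg.inv(T_A)
        mu = np.einsum("ijk,ik->ij", cov_A, b)
    except np.linalg.LinAlgError:
        jit = 1e-9 * np.maximum(1.0, np.einsum("ijj->i", T_A) / p)
        logger.warning("m_step: jittering %d precision matrices", p)
        T_A[:, diag, diag] += jit[:, None]
        cov_A = np.linalg.inv(T_A)
        mu = np.einsum("ijk,ik->ij", cov_A, b)

    n_trans = sum(ss.n_trans)
    n_obs = sum(ss.n_obs)
    u = np.full(p, hyper.u0 + 0.5 * n_trans)
    resid = sum(ss.s_diag) - np.einsum("ij,ij->i", b, mu)
    k = hyper.k0 + 0.5 * np.maximum(resid, 0.0)
    v = np.full(p, hyper.v0 + 0.5 * n_obs)
    l = hyper.l0 + 0.5 * np.maximum(sum(ss.obs_sq), 0.0)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(k)) and np.all(np.isfinite(l))):
        raise FloatingPointError(
            "non-finite sufficient statistics in M-step; the data are on a "
            "scale the model cannot handle — rescale or check for outliers"
        )

    d = edges.disagreement()
    z0, z1 = hyper.zeta_arrays(p)
    zeta0 = z0[:, None] + d
    zeta1 = z1[:, None] + (1.0 - d)

    return PosteriorTheta(
        mu_A=mu, prec_A=T_A, u=u, k=k, v=v, l=l,
        zeta0=zeta0, zeta1=zeta1, cov_A=cov_A,
    )


# ---------------------------------------------------------------------------
# A-step


def a_step(
    theta: PosteriorTheta,
    stats: LatentStats,
    edges: EdgePosterior,
    tau: float,
    hyper: HyperParams,
    data,
    n_sweeps: int = 5,
    suff: _SuffStats | None = None,
    maximize: bool = False,
) -> EdgePosterior:
    """Tempered mean-field updates of the edge posteriors.

    Each e_ij^(c) is set to the logistic of Delta_ij^(c) / tau, where Delta
    is the expected complete-log-joint gain of switching E_ij^(c) on:
    the system-likelihood term (linear in <A_ij/h_i>, quadratic through
    <A_ij A_ik / h_i> and the co-active probabilities e_ik), the
    coefficient-prior term through F_ij (coupling to the counterpart
    condition), and the potential term through <log z_ij> - <log(1-z_ij)>.
    Entries of a column can be updated simultaneously (rows are
    conditionally independent in the A-step); columns and conditions are
    swept sequentially, ``n_sweeps`` times.

    With ``maximize=True`` the update drops the tempered-entropy term and
    assigns each indicator to the endpoint with the larger expected
    complete log joint — the EM-style treatment of the indicators as
    parameters to be maximized rather than averaged over.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    ss = suff if suff is not None else _SuffStats(data, stats)
    p = theta.n_genes
    hinv = theta.h_inv_mean()
    mu = theta.mu_A
    # M2[i, j, k] = <A_ij A_ik / h_i>
    M2 = hinv[:, None, None] * mu[:, :, None] * mu[:, None, :] + theta.cov_A
    A2h = np.einsum("ijj->ij", M2)

    log_ratio = np.log(hyper.alpha1 / hyper.alpha0)
    prior_gain = -0.5 * log_ratio + 0.5 * A2h * (1.0 / hyper.alpha0 - 1.0 / hyper.alpha1)
    dlz = digamma(theta.zeta0) - digamma(theta.zeta1)  # <log z> - <log(1-z)>

    e = edges.e.copy()
    # per-condition tables: Lin[c][i,j] is the e-independent likelihood
    # gain, Q[c][i,j,k] = M2[i,j,k] Sxx_c[j,k] the co-activation penalty
    Lin = []
    Q = []
    for c in range(2):
        Sxx, Gxy = ss.Sxx[c], ss.Gxy[c]
        Lin.append(hinv[:, None] * mu * Gxy - 0.5 * A2h * np.diag(Sxx)[None, :])
        Q.append(M2 * Sxx[None, :, :])
    inv_tau = 1.0 / tau
    for _ in range(n_sweeps):
        for c in range(2):
            other = e[1 - c]
            ec = e[c]
            Qc = Q[c]
            # constant part of the gain; `other` is fixed while this
            # condition is swept
            const = Lin[c] + (1.0 - other) * prior_gain + (1.0 - 2.0 * other) * dlz
            Qdiag = np.einsum("ijj->ij", Qc)
            for j in range(p):
                # sum_{k != j} e_ik M2[i,j,k] Sxx[j,k]
                full = np.einsum("ik,ik->i", ec, Qc[:, j, :])
                full -= ec[:, j] * Qdiag[:, j]
                delta = const[:, j] - full
                if maximize:
                    ec[:, j] = np.where(delta > 0, 1.0 - _EPS, _EPS)
                else:
                    ec[:, j] = np.minimum(
                        np.maximum(expit(delta * inv_tau), _EPS), 1.0 - _EPS
                    )
    return EdgePosterior(e=e)


# ---------------------------------------------------------------------------
# hyperparameter updates (empirical Bayes, Newton-Raphson)


def update_hyper_ig(
    posterior_shapes: np.ndarray,
    posterior_inv_scales: np.ndarray,
    current: tuple[float, float] | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Maximize sum_i <log IG(h_i; u0, k0)> over (u0, k0).

    Uses <log h_i> = log k_i - psi(u_i) and <1/h_i> = u_i / k_i. The
    inverse scale profiles out as k0 = p u0 / sum<1/h_i>; the remaining
    1-d concave problem in u0 is solved by Newton-Raphson.
    """
    u_i = np.asarray(posterior_shapes, dtype=float)
    k_i = np.asarray(posterior_inv_scales, dtype=float)
    p = u_i.size
    e_log = np.log(k_i) - digamma(u_i)
    e_inv = u_i / k_i
    s_inv = e_inv.sum()
    lo, hi = 1e-3, 1e5
    # stationarity: log u0 - psi(u0) = mean<log h> + log(mean<1/h>); the
    # right side is >= 0 by Jensen and -> 0 when all posteriors coincide,
    # in which case the maximizer runs to the upper bound (a point-mass
    # prior) and is pinned there.
    rhs = e_log.mean() + np.log(s_inv / p)
    if not np.isfinite(rhs):
        if current is not None:
            logger.warning("update_hyper_ig: degenerate statistics, keeping previous")
            return current
        raise FloatingPointError("non-finite inverse-gamma statistics")
    if rhs <= 0.5 / hi:
        u0 = hi
    else:
        # Newton in log u0 (log u - psi(u) is monotone decreasing)
        u0 = min(max(0.5 / rhs, lo), hi)
        converged = False
        for _ in range(max_iter):
            g = np.log(u0) - digamma(u0) - rhs
            if abs(g) < 1e-12 * max(1.0, abs(rhs)):
                converged = True
                break
            dg_dlog = 1.0 - u0 * polygamma(1, u0)
            step = g / dg_dlog
            step = float(np.clip(step, -2.0, 2.0))
            new = float(np.clip(u0 * np.exp(-step), lo, hi))
            if abs(np.log(new) - np.log(u0)) < tol:
                u0 = new
                converged = True
                break
            u0 = new
        if not converged:
            if current is not None:
                logger.warning(
                    "update_hyper_ig: Newton did not converge, keeping previous"
                )
                return current
    k0 = p * u0 / s_inv
    return float(u0), float(k0)


def update_hyper_beta(
    zeta0_row: np.ndarray,
    zeta1_row: np.ndarray,
    current: tuple[float, float] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Maximize sum_j <log Beta(z_ij; zeta_i0, zeta_i1)> by 2-d Newton.

    Sufficient statistics are <log z_ij> = psi(zeta_ij0) - psi(zeta_ij0 +
    zeta_ij1) and the mirrored term; this is the classical Beta maximum
    likelihood problem with mean-log data.
    """
    a_post = np.asarray(zeta0_row, dtype=float)
    b_post = np.asarray(zeta1_row, dtype=float)
    p = a_post.size
    tot = digamma(a_post + b_post)
    mlz = (digamma(a_post) - tot).mean()
    ml1z = (digamma(b_post) - tot).mean()
    a, b = current if current is not None else (1.0, 1.0)
    for _ in range(max_iter):
        ga = digamma(a + b) - digamma(a) + mlz
        gb = digamma(a + b) - digamma(b) + ml1z
        t = polygamma(1, a + b)
        haa = t - polygamma(1, a)
        hbb = t - polygamma(1, b)
        det = haa * hbb - t * t
        if not np.isfinite(det) or abs(det) < 1e-300:
            break
        da = (hbb * ga - t * gb) / det
        db = (haa * gb - t * ga) / det
        scale = 1.0
        while a - scale * da <= 0 or b - scale * db <= 0:
            scale *= 0.5
            if scale < 1e-12:
                break
        a_new, b_new = a - scale * da, b - scale * db
        if abs(a_new - a) < tol * max(1.0, a) and abs(b_new - b) < tol * max(1.0, b):
            a, b = a_new, b_new
            return float(a), float(b)
        a, b = a_new, b_new
    if current is not None and (not np.isfinite(a) or not np.isfinite(b)):
        logger.warning("update_hyper_beta: Newton failed, keeping previous")
        return current
    return float(a), float(b)


def _beta_newton_rows(
    zeta0: np.ndarray,
    zeta1: np.ndarray,
    a0: np.ndarray,
    b0: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Beta empirical-Bayes update, all target genes at once.

    Same damped 2-d Newton as :func:`update_hyper_beta`, vectorized over
    the rows of the (p, p) posterior parameter matrices.
    """
    tot = digamma(zeta0 + zeta1)
    mlz = (digamma(zeta0) - tot).mean(axis=1)
    ml1z = (digamma(zeta1) - tot).mean(axis=1)
    a = a0.astype(float).copy()
    b = b0.astype(float).copy()
    for _ in range(max_iter):
        ga = digamma(a + b) - digamma(a) + mlz
        gb = digamma(a + b) - digamma(b) + ml1z
        t = polygamma(1, a + b)
        haa = t - polygamma(1, a)
        hbb = t - polygamma(1, b)
        det = haa * hbb - t * t
        safe = np.abs(det) > 1e-300
        da = np.where(safe, (hbb * ga - t * gb) / np.where(safe, det, 1.0), 0.0)
        db = np.where(safe, (haa * gb - t * ga) / np.where(safe, det, 1.0), 0.0)
        scale = np.ones_like(a)
        for _ in range(60):
            bad = (a - scale * da <= 0) | (b - scale * db <= 0)
            if not bad.any():
                break
            scale[bad] *= 0.5
        a_new = a - scale * da
        b_new = b - scale * db
        done = (np.abs(a_new - a) < tol * np.maximum(1.0, a)) & (
            np.abs(b_new - b) < tol * np.maximum(1.0, b)
        )
        a, b = a_new, b_new
        if done.all():
            break
    bad = ~(np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0))
    if bad.any():
        logger.warning("beta hyper update failed for %d rows, keeping previous",
                       int(bad.sum()))
        a[bad] = a0[bad]
        b[bad] = b0[bad]
    return a, b


def _update_hyperparameters(theta: PosteriorTheta, hyper: HyperParams) -> HyperParams:
    p = theta.n_genes
    u0, k0 = update_hyper_ig(theta.u, theta.k, current=(hyper.u0, hyper.k0))
    v0, l0 = update_hyper_ig(theta.v, theta.l, current=(hyper.v0, hyper.l0))
    z0_cur, z1_cur = hyper.zeta_arrays(p)
    z0, z1 = _beta_newton_rows(theta.zeta0, theta.zeta1, z0_cur, z1_cur)
    return replace(hyper, u0=u0, k0=k0, v0=v0, l0=l0, zeta0=z0, zeta1=z1)


# ---------------------------------------------------------------------------
# lower bound


def _ig_entropy(u: np.ndarray, k: np.ndarray) -> np.ndarray:
    return u + np.log(k) + gammaln(u) - (1.0 + u) * digamma(u)


def lower_bound(
    data,
    stats: LatentStats,
    theta: PosteriorTheta,
    edges: EdgePosterior,
    hyper: HyperParams,
    tau: float,
    suff: _SuffStats | None = None,
) -> tuple[float, float]:
    """Evaluate the annealed lower bound L_tau (and its tau=1 variant).

    Returns ``(tempered, plain)`` where the tempered value weights the
    Q(E) entropy by tau (the functional each sweep maximizes at fixed tau)
    and the plain value uses the ordinary entropy.
    """
    ss = suff if suff is not None else _SuffStats(data, stats)
    p = theta.n_genes
    hinv = theta.h_inv_mean()
    rinv = theta.r_inv_mean()
    e_log_h = np.log(theta.k) - digamma(theta.u)
    e_log_r = np.log(theta.l) - digamma(theta.v)
    mu = theta.mu_A
    M2 = hinv[:, None, None] * mu[:, :, None] * mu[:, None, :] + theta.cov_A
    A2h = np.einsum("ijj->ij", M2)
    diag = np.arange(p)

    elogp = 0.0
    for c in range(2):
        e = edges.e[c]
        n_tr = ss.n_trans[c]
        quad = float((hinv * ss.s_diag[c]).sum())
        quad -= 2.0 * float((hinv[:, None] * e * mu * ss.Gxy[c]).sum())
        EE = e[:, :, None] * e[:, None, :]
        EE[:, diag, diag] = e
        Omega = np.einsum("ijk,ijk->jk", EE, M2)
        quad += float((Omega * ss.Sxx[c]).sum())
        elogp += -0.5 * n_tr * (p * LOG2PI + e_log_h.sum()) - 0.5 * quad
        n_ob = ss.n_obs[c]
        elogp += -0.5 * n_ob * (p * LOG2PI + e_log_r.sum())
        elogp += -0.5 * float((rinv * ss.obs_sq[c]).sum())

    f = edges.f()
    e_log_alpha = f * np.log(hyper.alpha1) + (1.0 - f) * np.log(hyper.alpha0)
    e_inv_alpha = f / hyper.alpha1 + (1.0 - f) / hyper.alpha0
    elogp += float(
        (
            -0.5 * (LOG2PI + e_log_h[:, None] + e_log_alpha)
            - 0.5 * A2h * e_inv_alpha
        ).sum()
    )
    elogp += float(
        (hyper.u0 * np.log(hyper.k0) - gammaln(hyper.u0)
         - (hyper.u0 + 1.0) * e_log_h - hyper.k0 * hinv).sum()
    )
    elogp += float(
        (hyper.v0 * np.log(hyper.l0) - gammaln(hyper.v0)
         - (hyper.v0 + 1.0) * e_log_r - hyper.l0 * rinv).sum()
    )

    psi_tot = digamma(theta.zeta0 + theta.zeta1)
    e_lz = digamma(theta.zeta0) - psi_tot
    e_l1z = digamma(theta.zeta1) - psi_tot
    d = edges.disagreement()
    elogp += float((np.log(0.5) + d * e_lz + (1.0 - d) * e_l1z).sum())
    z0, z1 = hyper.zeta_arrays(p)
    elogp += float(
        (
            -betaln(z0, z1)[:, None]
            + (z0[:, None] - 1.0) * e_lz
            + (z1[:, None] - 1.0) * e_l1z
        ).sum()
    )

    # entropies
    h_x = 0.0
    for c in range(2):
        sm = stats[c]
        n = p * sm.n_steps
        h_x += 0.5 * (n * (1.0 + LOG2PI) - sm.logdet_precision)
    sign, logdet_T = np.linalg.slogdet(theta.prec_A)
    h_ah = float(
        (
            0.5 * p * (1.0 + LOG2PI)
            + 0.5 * p * e_log_h
            - 0.5 * logdet_T
            + _ig_entropy(theta.u, theta.k)
        ).sum()
    )
    h_r = float(_ig_entropy(theta.v, theta.l).sum())
    h_z = float(
        (
            betaln(theta.zeta0, theta.zeta1)
            - (theta.zeta0 - 1.0) * digamma(theta.zeta0)
            - (theta.zeta1 - 1.0) * digamma(theta.zeta1)
            + (theta.zeta0 + theta.zeta1 - 2.0) * psi_tot
        ).sum()
    )
    ec = np.clip(edges.e, _EPS, 1.0 - _EPS)
    h_e = float(-(ec * np.log(ec) + (1.0 - ec) * np.log1p(-ec)).sum())

    base = elogp + h_x + h_ah + h_r + h_z
    return base + tau * h_e, base + h_e


# ---------------------------------------------------------------------------
# driver loops


def _initial_stats(data) -> LatentStats:
    """Initialize <x> from observations, linearly interpolated at
    unobserved grid points; second moments start as outer products."""
    per = []
    for series in data:
        grid = series.grid
        p, T = series.n_genes, grid.n_grid
        t_all = np.arange(1, T + 1, dtype=float)
        t_obs = np.asarray(grid.observed, dtype=float)
        mean = np.empty((p, T))
        for i in range(p):
            mean[i] = np.interp(t_all, t_obs, series.values[i])
        second = np.einsum("it,jt->tij", mean, mean)
        cross = mean[:, 1:].T[:, :, None] * mean[:, :-1].T[:, None, :]
        per.append(
            SmoothedMoments(mean=mean, second=second, cross=cross,
                            logdet_precision=np.nan)
        )
    return LatentStats(per_condition=(per[0], per[1]))


def _check_data(data):
    if len(data) != 2:
        raise ValueError("exactly two observed series (one per condition) required")
    if data[0].n_genes != data[1].n_genes:
        raise ValueError("both conditions must measure the same genes")


def _fit_loop(
    data,
    hyper: HyperParams,
    sched: AnnealSchedule,
    temperatures,
    update_hyper: bool,
    n_asweeps: int,
    maximize_e: bool = False,
) -> FitResult:
    _check_data(data)
    p = data[0].n_genes
    hyper_cur = replace(hyper)
    edges = EdgePosterior(e=np.full((2, p, p), 0.5))
    stats = _initial_stats(data)
    trace: list = []
    trace_plain: list = []
    theta = None
    suff = _SuffStats(data, stats)
    for tau in temperatures:
        prev_bound = None
        for _ in range(sched.inner_max):
            theta = m_step(stats, edges, hyper_cur, data, suff=suff)
            if update_hyper:
                hyper_cur = _update_hyperparameters(theta, hyper_cur)
            stats, _ = smooth_pair(data, theta, edges)
            suff = _SuffStats(data, stats)
            edges = a_step(theta, stats, edges, tau, hyper_cur, data,
                           n_sweeps=n_asweeps, suff=suff, maximize=maximize_e)
            bound, plain = lower_bound(data, stats, theta, edges, hyper_cur, tau,
                                       suff=suff)
            if not np.isfinite(bound):
                raise FloatingPointError(
                    f"lower bound became non-finite at tau={tau:.4f}"
                )
            trace.append((tau, bound))
            trace_plain.append((tau, plain))
            if prev_bound is not None and abs(bound - prev_bound) <= (
                sched.inner_tol * max(1.0, abs(bound))
            ):
                break
            prev_bound = bound
    networks = edges.networks(theta.mu_A)
    return FitResult(
        theta=theta, edges=edges, stats=stats, hyper=hyper_cur,
        bound_trace=trace, bound_trace_plain=trace_plain, networks=networks,
    )


def anneal_fit(
    data,
    hyper: HyperParams | None = None,
    sched: AnnealSchedule | None = None,
    seed: int = 0,
    update_hyper: bool = True,
    n_asweeps: int = 5,
) -> FitResult:
    """Full variational-annealing fit of the joint network model.

    Runs the annealing loop — per inner cycle: M-step, hyperparameter
    updates, E-step, A-step — to convergence at each temperature, cooling
    tau from ``sched.tau_init`` by ``sched.cool_factor`` until
    ``sched.tau_min``. The fit is deterministic given data and
    configuration; ``seed`` is accepted for interface parity with
    stochastic drivers.
    """
    hyper = hyper or HyperParams()
    sched = sched or AnnealSchedule()
    return _fit_loop(data, hyper, sched, sched.temperatures(),
                     update_hyper, n_asweeps)


def em_fit(
    data,
    hyper: HyperParams | None = None,
    sched: AnnealSchedule | None = None,
    seed: int = 0,
    update_hyper: bool = True,
    n_asweeps: int = 5,
) -> FitResult:
    """Non-annealed EM-style baseline: one temperature, indicators maximized.

    The loop is identical to :func:`anneal_fit` but runs at a single
    recorded temperature and treats the edge indicators as parameters:
    each cycle assigns every e_ij^(c) to the endpoint of (0, 1) with the
    larger expected complete log joint instead of tempered averaging, and
    the result is discretized at 0.5. Without the annealing path this
    greedy maximization commits to borderline edges early, which is why
    it retains more false positives than the annealed fit.
    """
    hyper = hyper or HyperParams()
    sched = sched or AnnealSchedule()
    return _fit_loop(data, hyper, sched, [1.0], update_hyper, n_asweeps,
                     maximize_e=True)


def select_alpha0(
    data,
    alpha0_grid,
    hyper: HyperParams | None = None,
    sched: AnnealSchedule | None = None,
    seed: int = 0,
    stride: int = 1,
    update_hyper: bool = True,
    method: str = "anneal",
    return_table: bool = False,
):
    """Choose alpha0 by leave-one-time-point-out cross validation.

    For every alpha0 on the grid and every observed time point t of each
    condition (optionally every ``stride``-th point, to control cost), the
    model is refit with y_t held out and the squared residual between y_t
    and the smoothed prediction of x_t is accumulated; the alpha0 with the
    smallest total residual wins (ties break toward smaller alpha0). The
    final observed point of each condition anchors the grid and is never
    held out.
    """
    alpha0_grid = sorted(float(a) for a in alpha0_grid)
    if not alpha0_grid:
        raise ValueError("alpha0 grid must be non-empty")
    hyper = hyper or HyperParams()
    sched = sched or AnnealSchedule()
    if any(a >= hyper.alpha1 for a in alpha0_grid):
        raise ValueError("every alpha0 must be below alpha1")
    fit = anneal_fit if method == "anneal" else em_fit

    totals = []
    table = []
    for a0 in alpha0_grid:
        hyp = replace(hyper, alpha0=a0)
        total = 0.0
        for c in range(2):
            series = data[c]
            grid = series.grid
            holdouts = grid.observed[:-1][::stride]
            for t in holdouts:
                pos = grid.observed.index(t)
                new_obs = tuple(s for s in grid.observed if s != t)
                new_grid = TimeGrid(
                    n_grid=grid.n_grid, observed=new_obs, interval=grid.interval
                )
                reduced = ObservedSeries(
                    values=np.delete(series.values, pos, axis=1),
                    grid=new_grid, condition=series.condition,
                )
                pair = (reduced, data[1 - c]) if c == 0 else (data[1 - c], reduced)
                res = fit(pair, hyp, sched, seed=seed, update_hyper=update_hyper)
                pred = res.stats[c].mean[:, t - 1]
                r2 = float(((series.values[:, pos] - pred) ** 2).sum())
                total += r2
                table.append({"alpha0": a0, "condition": c + 1, "t": t, "r2": r2})
        totals.append(total)
        logger.info("alpha0 CV: alpha0=%g total squared residual=%g", a0, total)
    best = alpha0_grid[int(np.argmin(totals))]
    if return_table:
        return best, table
    return best
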