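"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the model equations directly
(scipy densities, dense linear algebra, explicit enumeration), not via the
package's own vectorized implementations, so tests compare two separate
code paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as st


def log_joint_oracle(data, X, A, h, r, z, E, hyper):
    """Complete-data log joint via per-element scipy density calls."""
    p = A.shape[0]
    total = 0.0
    for c in range(2):
        series, x = data[c], X[c]
        grid = series.grid
        B = A * E[c]
        for t in range(1, grid.n_grid):
            pred = B @ x[:, t - 1]
            for i in range(p):
                total += st.norm.logpdf(x[i, t], pred[i], np.sqrt(h[i]))
        for col, t in enumerate(grid.observed):
            for i in range(p):
                total += st.norm.logpdf(
                    series.values[i, col], x[i, t - 1], np.sqrt(r[i])
                )
    for i in range(p):
        for j in range(p):
            F = 1 if (E[0][i, j] or E[1][i, j]) else 0
            alpha = hyper.alpha1 if F else hyper.alpha0
            total += st.norm.logpdf(A[i, j], 0.0, np.sqrt(h[i] * alpha))
    for i in range(p):
        total += st.invgamma.logpdf(h[i], hyper.u0, scale=hyper.k0)
        total += st.invgamma.logpdf(r[i], hyper.v0, scale=hyper.l0)
    z0, z1 = hyper.zeta_arrays(p)
    for i in range(p):
        for j in range(p):
            mass = z[i, j] if E[0][i, j] != E[1][i, j] else 1.0 - z[i, j]
            total += np.log(0.5 * mass)
            total += st.beta.logpdf(z[i, j], z0[i], z1[i])
    return total


def dense_gaussian_moments(series, sys):
    """Posterior moments of the hidden trajectory by dense inversion.

    Builds the full (p T x p T) precision matrix of the Gaussian chain
    defined by the expected system matrices and inverts it outright.
    """
    grid = series.grid
    p = series.values.shape[0]
    T = grid.n_grid
    n = p * T
    J = np.zeros((n, n))
    b = np.zeros(n)
    Hinv = np.diag(sys.Hinv)
    Rinv = np.diag(sys.Rinv)
    for t in range(T - 1):
        s0, s1 = t * p, (t + 1) * p
        J[s1:s1 + p, s1:s1 + p] += Hinv
        J[s0:s0 + p, s0:s0 + p] += sys.AEHAE
        J[s1:s1 + p, s0:s0 + p] += -sys.HinvAE
        J[s0:s0 + p, s1:s1 + p] += -sys.HinvAE.T
    for col, t in enumerate(grid.observed):
        s = (t - 1) * p
        J[s:s + p, s:s + p] += Rinv
        b[s:s + p] += sys.Rinv * series.values[:, col]
    cov = np.linalg.inv(J)
    mean_flat = cov @ b
    mean = mean_flat.reshape(T, p).T
    second = np.empty((T, p, p))
    cross = np.empty((T - 1, p, p))
    for t in range(T):
        s = t * p
        mm = np.outer(mean[:, t], mean[:, t])
        second[t] = cov[s:s + p, s:s + p] + mm
    for t in range(T - 1):
        s0, s1 = t * p, (t + 1) * p
        cross[t] = cov[s1:s1 + p, s0:s0 + p] + np.outer(mean[:, t + 1], mean[:, t])
    sign, logdet = np.linalg.slogdet(J)
    return mean, second, cross, logdet


def rts_smoother(y, B, H, R, m0, P0):
    """Textbook Kalman filter + RTS smoother, fully observed grid.

    y: (p, T) observations, B: transition matrix, H/R: diagonal system and
    observation covariances (vectors), x_1 ~ N(m0, P0).
    """
    p, T = y.shape
    Hm, Rm = np.diag(H), np.diag(R)
    m_pred, P_pred, m_filt, P_filt = [], [], [], []
    for t in range(T):
        if t == 0:
            mp, Pp = m0, P0
        else:
            mp = B @ m_filt[-1]
            Pp = B @ P_filt[-1] @ B.T + Hm
        S = Pp + Rm
        K = Pp @ np.linalg.inv(S)
        mf = mp + K @ (y[:, t] - mp)
        Pf = (np.eye(p) - K) @ Pp
        m_pred.append(mp); P_pred.append(Pp); m_filt.append(mf); P_filt.append(Pf)
    ms = [None] * T
    Ps = [None] * T
    cross = [None] * (T - 1)
    ms[-1], Ps[-1] = m_filt[-1], P_filt[-1]
    for t in range(T - 2, -1, -1):
        G = P_filt[t] @ B.T @ np.linalg.inv(P_pred[t + 1])
        ms[t] = m_filt[t] + G @ (ms[t + 1] - m_pred[t + 1])
        Ps[t] = P_filt[t] + G @ (Ps[t + 1] - P_pred[t + 1]) @ G.T
        cross[t] = Ps[t + 1] @ G.T  # cov(x_{t+1}, x_t)
    return np.array(ms).T, np.array(Ps), np.array(cross)


def count_confusion(est, truth):
    """Shared enumeration oracle for edge and change metrics."""
    p = truth[0].edges.shape[0]
    edge_tp = edge_fp = 0
    for c in range(2):
        for i in range(p):
            for j in range(p):
                if est[c].edges[i, j]:
                    if truth[c].edges[i, j]:
                        edge_tp += 1
                    else:
                        edge_fp += 1
    change_tp = change_fp = 0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            e1, e2 = est[0].edges[i, j], est[1].edges[i, j]
            t1, t2 = truth[0].edges[i, j], truth[1].edges[i, j]
            if e1 == e2:
                continue
            pred_cond = 1 if e1 else 2
            true_change = t1 != t2
            true_cond = (1 if t1 else 2) if true_change else None
            if true_change and pred_cond == true_cond:
                change_tp += 1
            else:
                change_fp += 1
    return edge_tp, edge_fp, change_tp, change_fp


# ---------------------------------------------------------------------------
# brute-force marginal-likelihood oracle over all 2^(2 p^2) edge
# configurations (p = 3): Theta is integrated in closed form given a
# trajectory sample (row-wise normal-inverse-gamma for (A_i, h_i), inverse
# gamma for r_i, Beta-potential for z_ij); the trajectory X is integrated
# by common-random-number importance sampling so that the ranking of
# configurations is stable; a tensor contraction scores every
# configuration at once.

from scipy.special import betaln as _betaln, gammaln as _gammaln


def chain_precision(series, sys):
    """Dense precision and linear term of the Gaussian chain posterior."""
    p = series.values.shape[0]
    T = series.grid.n_grid
    n = p * T
    J = np.zeros((n, n))
    b = np.zeros(n)
    for t in range(T - 1):
        s0, s1 = t * p, (t + 1) * p
        J[s1:s1 + p, s1:s1 + p] += np.diag(sys.Hinv)
        J[s0:s0 + p, s0:s0 + p] += sys.AEHAE
        J[s1:s1 + p, s0:s0 + p] -= sys.HinvAE
        J[s0:s0 + p, s1:s1 + p] -= sys.HinvAE.T
    for col, t in enumerate(series.grid.observed):
        s = (t - 1) * p
        J[s:s + p, s:s + p] += np.diag(sys.Rinv)
        b[s:s + p] += sys.Rinv * series.values[:, col]
    return J, b


def sample_trajectories(data, fit, n_samples, rng, inflate=1.2):
    """Sample X from the fitted Q(X) (inflated) as the IS proposal."""
    from diffvar.kalman import expected_system

    X, log_g = [], np.zeros(n_samples)
    systems = expected_system(fit.theta, fit.edges)
    for c in range(2):
        p = data[c].values.shape[0]
        T = data[c].grid.n_grid
        n = p * T
        J, b = chain_precision(data[c], systems[c])
        mean = np.linalg.solve(J, b)
        Js = J / inflate**2
        L = np.linalg.cholesky(Js)
        eps = rng.standard_normal((n_samples, n))
        dev = np.linalg.solve(L.T[None], eps[:, :, None])[:, :, 0]
        x = mean[None] + dev
        sign, ldJ = np.linalg.slogdet(Js)
        log_g += -0.5 * (eps**2).sum(axis=1) + 0.5 * ldJ - 0.5 * n * np.log(2 * np.pi)
        X.append(x.reshape(n_samples, T, p).transpose(0, 2, 1))
    return X, log_g


def marginal_tables(data, hyper, X, log_g):
    """Per-row log integrand tables over trajectory samples.

    Returns (lw, L, zrow): log P(Y, E) ~ logsumexp_s [lw_s + sum_i
    L[i][s, combo_i]] + sum_i zrow[combo_i], where combo_i encodes the
    6 indicator bits of target row i over both conditions.
    """
    p = 3
    S = len(log_g)
    lw = -log_g
    M_obs = sum(d.grid.n_observed for d in data)
    for i in range(p):
        ssr = np.zeros(S)
        for c in range(2):
            idx = np.asarray(data[c].grid.observed) - 1
            ssr += ((data[c].values[i][None] - X[c][:, i, idx])**2).sum(axis=1)
        lw += (-0.5 * M_obs * np.log(2 * np.pi) + hyper.v0 * np.log(hyper.l0)
               - _gammaln(hyper.v0) + _gammaln(hyper.v0 + M_obs / 2)
               - (hyper.v0 + M_obs / 2) * np.log(hyper.l0 + ssr / 2))
    Sxx, Cx, s2 = [], [], []
    N = 0
    for c in range(2):
        xc = X[c]
        prev, cur = xc[:, :, :-1], xc[:, :, 1:]
        Sxx.append(np.einsum('sit,sjt->sij', prev, prev))
        Cx.append(np.einsum('sit,sjt->sij', cur, prev))
        s2.append((cur**2).sum(axis=2))
        N += xc.shape[2] - 1
    combos = [(np.array([(a >> b) & 1 for b in range(p)], float),
               np.array([(a >> (b + p)) & 1 for b in range(p)], float))
              for a in range(64)]
    L = np.empty((p, S, 64))
    zrow = np.empty(64)
    z0 = float(np.broadcast_to(np.asarray(hyper.zeta0, float), (p,))[0])
    z1 = float(np.broadcast_to(np.asarray(hyper.zeta1, float), (p,))[0])
    for a, (m1, m2) in enumerate(combos):
        F = np.maximum(m1, m2)
        alpha = np.where(F > 0, hyper.alpha1, hyper.alpha0)
        d = (m1 != m2).astype(float)
        zrow[a] = np.log(0.5) * p + (_betaln(z0 + d, z1 + 1 - d) - _betaln(z0, z1)).sum()
        W = (m1[:, None] * m1[None, :]) * Sxx[0] + (m2[:, None] * m2[None, :]) * Sxx[1]
        T = W + np.diag(1.0 / alpha)[None]
        sign, ld = np.linalg.slogdet(T)
        for i in range(p):
            bvec = m1 * Cx[0][:, i, :] + m2 * Cx[1][:, i, :]
            sol = np.linalg.solve(T, bvec[:, :, None])[:, :, 0]
            delta = s2[0][:, i] + s2[1][:, i] - (bvec * sol).sum(axis=1)
            L[i, :, a] = (-0.5 * N * np.log(2 * np.pi) - 0.5 * np.log(alpha).sum()
                          - 0.5 * ld + hyper.u0 * np.log(hyper.k0)
                          - _gammaln(hyper.u0) + _gammaln(hyper.u0 + N / 2)
                          - (hyper.u0 + N / 2) * np.log(hyper.k0 + np.maximum(delta, 1e-12) / 2))
    return lw, L, zrow


def brute_force_log_marginals(lw, L, zrow):
    """Score all 64^3 configurations; returns the (64, 64, 64) log-marginal
    tensor indexed by the per-row combo codes."""
    w = np.exp(lw - lw.max())
    sh = L.max(axis=(1, 2))
    F1, F2, F3 = (np.exp(L[i] - sh[i]) for i in range(3))
    M = np.einsum('s,sa,sb,sc->abc', w, F1, F2, F3)
    return (np.log(np.maximum(M, 1e-300))
            + zrow[:, None, None] + zrow[None, :, None] + zrow[None, None, :])


def encode_config(E1, E2, p=3):
    """Row-wise combo codes of a binary configuration pair."""
    return tuple(
        int(sum(int(E1[i, b]) << b for b in range(p))
            + sum(int(E2[i, b]) << (b + p) for b in range(p)))
        for i in range(p)
    )
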