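"""M-step conjugacy, tempered A-step, hyperparameter updates, and the
annealing / fixed-temperature drivers."""

import numpy as np
import pytest
from scipy.special import betaln, digamma, gammaln, logit

import diffvar as dv
from diffvar.annealing import (
    _initial_stats,
    a_step,
    em_fit,
    lower_bound,
    m_step,
    select_alpha0,
    update_hyper_beta,
    update_hyper_ig,
)
from diffvar.kalman import smooth_pair
from diffvar.model import EdgePosterior, LatentStats, SmoothedMoments
from conftest import small_pair


def _stats_from_trajectories(X_pair):
    """Point-mass LatentStats built directly from given trajectories."""
    per = []
    for x in X_pair:
        second = np.einsum("it,jt->tij", x, x)
        cross = np.einsum("it,jt->tij", x[:, 1:], x[:, :-1])
        per.append(SmoothedMoments(mean=x, second=second, cross=cross))
    return LatentStats(per_condition=tuple(per))


def _series_pair_from(X_pair):
    out = []
    for c, x in enumerate(X_pair):
        grid = dv.TimeGrid.equal(x.shape[1])
        out.append(dv.ObservedSeries(x, grid, c + 1))
    return tuple(out)


class TestMStep:
    def test_no_transitions_recovers_prior(self):
        # a single time point provides no regression information: the
        # coefficient posterior must collapse onto the (expected) prior
        p = 3
        x = [np.zeros((p, 1)), np.zeros((p, 1))]
        stats = _stats_from_trajectories(x)
        data = _series_pair_from(x)
        e = np.full((2, p, p), 0.3)
        hyper = dv.HyperParams(alpha0=0.5, alpha1=20.0)
        theta = m_step(stats, EdgePosterior(e=e), hyper, data)
        assert np.allclose(theta.mu_A, 0.0)
        f = dv.indicator_F(e[0], e[1])
        expected_prec = f / hyper.alpha1 + (1 - f) / hyper.alpha0
        for i in range(p):
            assert np.allclose(theta.prec_A[i], np.diag(expected_prec[i]))
        assert np.allclose(theta.u, hyper.u0)
        assert np.allclose(theta.k, hyper.k0)

    def test_matches_pooled_ols_with_edges_on_and_flat_prior(self, rng):
        # hard edges, point-mass states, alpha1 -> infinity: the posterior
        # mean must equal the ordinary least-squares VAR estimate pooled
        # over both conditions
        p, T = 3, 40
        A = np.array([[0.5, 0.2, 0.0], [0.0, -0.4, 0.3], [0.1, 0.0, 0.6]])
        X = []
        for _ in range(2):
            x = np.zeros((p, T))
            for t in range(1, T):
                x[:, t] = A @ x[:, t - 1] + rng.normal(size=p)
            X.append(x)
        stats = _stats_from_trajectories(X)
        data = _series_pair_from(X)
        hyper = dv.HyperParams(alpha0=1e10, alpha1=1e12)
        edges = EdgePosterior(e=np.ones((2, p, p)) - 1e-12)
        theta = m_step(stats, edges, hyper, data)
        preds = np.hstack([x[:, :-1] for x in X])
        targets = np.hstack([x[:, 1:] for x in X])
        ols = np.linalg.lstsq(preds.T, targets.T, rcond=None)[0].T
        assert np.allclose(theta.mu_A, ols, atol=1e-4)

    def test_beta_updates_count_hard_assignments(self):
        p = 2
        x = [np.zeros((p, 2)), np.zeros((p, 2))]
        stats = _stats_from_trajectories(x)
        data = _series_pair_from(x)
        e = np.zeros((2, p, p))
        e[0, 0, 1] = 1.0   # disagreement at (0, 1)
        e[1, 1, 0] = 1.0   # disagreement at (1, 0)
        e[0, 0, 0] = e[1, 0, 0] = 1.0   # agreement (both on) at (0, 0)
        hyper = dv.HyperParams(zeta0=4.0, zeta1=7.0)
        theta = m_step(stats, EdgePosterior(e=e), hyper, data)
        assert theta.zeta0[0, 1] == pytest.approx(5.0)   # 4 + [disagree]
        assert theta.zeta1[0, 1] == pytest.approx(7.0)
        assert theta.zeta0[0, 0] == pytest.approx(4.0)
        assert theta.zeta1[0, 0] == pytest.approx(8.0)   # 7 + [agree]
        assert theta.zeta0[1, 1] == pytest.approx(4.0)   # both off: agree
        assert theta.zeta1[1, 1] == pytest.approx(8.0)

    def test_observation_noise_update_pools_residuals(self, rng):
        p, T = 2, 8
        X = [rng.normal(size=(p, T)), rng.normal(size=(p, T))]
        stats = _stats_from_trajectories(X)
        grid = dv.TimeGrid.equal(T)
        data = tuple(
            dv.ObservedSeries(X[c] + rng.normal(scale=0.3, size=(p, T)), grid, c + 1)
            for c in range(2)
        )
        hyper = dv.HyperParams()
        theta = m_step(stats, EdgePosterior(e=np.full((2, p, p), 0.5)), hyper, data)
        ssr = sum(((data[c].values - X[c]) ** 2).sum(axis=1) for c in range(2))
        assert np.allclose(theta.v, hyper.v0 + T)
        assert np.allclose(theta.l, hyper.l0 + 0.5 * ssr)


class TestAStep:
    def test_infinite_temperature_flattens_posteriors(self):
        data, _ = small_pair(seed=3, p=3, T=10)
        stats = _initial_stats(data)
        hyper = dv.HyperParams()
        edges = EdgePosterior(e=np.full((2, 3, 3), 0.5))
        theta = m_step(stats, edges, hyper, data)
        out = a_step(theta, stats, edges, tau=1e12, hyper=hyper, data=data)
        assert np.allclose(out.e, 0.5, atol=1e-9)

    def test_gain_matches_bound_endpoint_difference(self, rng):
        # the logistic gain of each first-column update must equal the
        # lower-bound difference between the two Bernoulli endpoints
        data, _ = small_pair(seed=5, p=3, T=10)
        hyper = dv.HyperParams(alpha0=0.5, alpha1=50.0, zeta0=2.0, zeta1=4.0)
        edges = EdgePosterior(e=rng.uniform(0.2, 0.8, (2, 3, 3)))
        stats = _initial_stats(data)
        theta = m_step(stats, edges, hyper, data)
        stats, _ = smooth_pair(data, theta, edges)
        tau = 1.7
        out = a_step(theta, stats, EdgePosterior(e=edges.e.copy()), tau, hyper,
                     data, n_sweeps=1)
        for i in range(3):
            vals = []
            for v in (1.0 - 1e-12, 1e-12):
                e2 = edges.e.copy()
                e2[0, i, 0] = v
                b, _ = lower_bound(data, stats, theta, EdgePosterior(e=e2),
                                   hyper, tau)
                vals.append(b)
            implied = logit(out.e[0, i, 0]) * tau
            assert implied == pytest.approx(vals[0] - vals[1], abs=1e-7)

    def test_strong_single_regulation_detected(self):
        # one strong cross-regulation on two genes: the annealed posterior
        # must saturate for the true edge and vanish for absent ones
        p, T = 2, 20
        rng = np.random.default_rng(11)
        A = np.array([[0.6, 0.0], [0.85, 0.5]])   # gene 0 -> gene 1
        E = (A != 0).astype(int)
        net = dv.NetworkModel(coeff=A, edges=E)
        data = tuple(
            dv.simulate_series(net, T, 1.0, 0.1, seed=rng, condition=c + 1)
            for c in range(2)
        )
        fit = dv.anneal_fit(data, hyper=dv.HyperParams(alpha0=0.01))
        for c in range(2):
            assert fit.edges.e[c][1, 0] > 0.99
            assert fit.edges.e[c][0, 1] < 0.01

    def test_fixed_point_is_coordinatewise_optimal(self, rng):
        # iterate the soft tau=1 sweep to a fixed point: the converged
        # edge posteriors must maximize the bound along every coordinate
        # (mean-field fixed point), checked against a 1-d grid scan
        data, _ = small_pair(seed=7, p=2, T=15)
        hyper = dv.HyperParams(alpha0=0.1, alpha1=50.0)
        edges = EdgePosterior(e=np.full((2, 2, 2), 0.5))
        stats = _initial_stats(data)
        prev = None
        for _ in range(80):
            theta = m_step(stats, edges, hyper, data)
            stats, _ = smooth_pair(data, theta, edges)
            edges = a_step(theta, stats, edges, 1.0, hyper, data)
            b, _ = lower_bound(data, stats, theta, edges, hyper, 1.0)
            if prev is not None and abs(b - prev) < 1e-10 * max(1.0, abs(b)):
                break
            prev = b
        base, _ = lower_bound(data, stats, theta, edges, hyper, 1.0)
        grid = np.linspace(1e-6, 1 - 1e-6, 41)
        for c in range(2):
            for i in range(2):
                for j in range(2):
                    vals = []
                    for g in grid:
                        e2 = edges.e.copy()
                        e2[c, i, j] = g
                        b, _ = lower_bound(data, stats, theta,
                                           EdgePosterior(e=e2), hyper, 1.0)
                        vals.append(b)
                    assert base >= max(vals) - 1e-6


def _ig_objective(u_i, k_i, u0, k0):
    e_log = np.log(k_i) - digamma(u_i)
    e_inv = u_i / k_i
    return float(
        (u0 * np.log(k0) - gammaln(u0) - (u0 + 1) * e_log - k0 * e_inv).sum()
    )


def _beta_objective(z0_row, z1_row, a, b):
    tot = digamma(z0_row + z1_row)
    e_lz = digamma(z0_row) - tot
    e_l1z = digamma(z1_row) - tot
    return float(((a - 1) * e_lz + (b - 1) * e_l1z - betaln(a, b)).sum())


class TestHyperUpdates:
    def test_ig_self_consistency(self):
        # identical posteriors: the maximizing prior is that posterior
        u = np.full(4, 3.0)
        k = np.full(4, 2.0)
        u0, k0 = update_hyper_ig(u, k)
        assert u0 == pytest.approx(3.0, rel=1e-6)
        assert k0 == pytest.approx(2.0, rel=1e-6)

    def test_ig_beats_grid(self, rng):
        u = rng.uniform(2.0, 8.0, 3)
        k = rng.uniform(0.5, 5.0, 3)
        u0, k0 = update_hyper_ig(u, k)
        best = _ig_objective(u, k, u0, k0)
        for gu in np.logspace(-1, 1.5, 100):
            for gk in np.logspace(-1, 1.5, 100):
                assert best >= _ig_objective(u, k, gu, gk) - 1e-9

    def test_ig_stationarity(self, rng):
        u = rng.uniform(2.0, 8.0, 5)
        k = rng.uniform(0.5, 5.0, 5)
        u0, k0 = update_hyper_ig(u, k)
        eps = 1e-5
        for du, dk in ((eps, 0), (0, eps)):
            g = (
                _ig_objective(u, k, u0 + du, k0 + dk)
                - _ig_objective(u, k, u0 - du, k0 - dk)
            ) / (2 * eps)
            assert abs(g) < 1e-4

    def test_beta_self_consistency(self):
        z0 = np.full(5, 4.0)
        z1 = np.full(5, 2.5)
        a, b = update_hyper_beta(z0, z1, current=(1.0, 1.0))
        assert a == pytest.approx(4.0, rel=1e-5)
        assert b == pytest.approx(2.5, rel=1e-5)

    def test_beta_beats_grid(self, rng):
        z0 = rng.uniform(1.0, 6.0, 4)
        z1 = rng.uniform(1.0, 6.0, 4)
        a, b = update_hyper_beta(z0, z1, current=(2.0, 2.0))
        best = _beta_objective(z0, z1, a, b)
        for ga in np.logspace(-0.5, 1.2, 100):
            for gb in np.logspace(-0.5, 1.2, 100):
                assert best >= _beta_objective(z0, z1, ga, gb) - 1e-9

    def test_beta_stationarity(self, rng):
        z0 = rng.uniform(1.0, 6.0, 4)
        z1 = rng.uniform(1.0, 6.0, 4)
        a, b = update_hyper_beta(z0, z1, current=(2.0, 2.0))
        eps = 1e-5
        for da, db in ((eps, 0), (0, eps)):
            g = (
                _beta_objective(z0, z1, a + da, b + db)
                - _beta_objective(z0, z1, a - da, b - db)
            ) / (2 * eps)
            assert abs(g) < 1e-4


class TestDrivers:
    def test_identical_conditions_give_identical_networks(self):
        data, _ = small_pair(seed=1, p=5, T=25, obs_sd=0.1, n_specific=0)
        # feed condition 1's series to both slots
        twin = (data[0], dv.ObservedSeries(data[0].values, data[0].grid, 2))
        fit = dv.anneal_fit(twin)
        assert np.array_equal(fit.networks[0].edges, fit.networks[1].edges)
        m = dv.change_metrics(fit.networks, fit.networks)
        assert m.tp == 0 and m.fp == 0

    def test_em_runs_single_temperature_with_same_interfaces(self):
        data, _ = small_pair(seed=2, p=3, T=10)
        fa = dv.anneal_fit(data)
        fe = em_fit(data)
        assert {t for t, _ in fe.bound_trace} == {1.0}
        assert fe.theta.mu_A.shape == fa.theta.mu_A.shape
        assert fe.edges.e.shape == fa.edges.e.shape
        assert len(fe.networks) == len(fa.networks) == 2

    def test_bound_never_decreases_within_temperature(self):
        sched = dv.AnnealSchedule(tau_min=0.3, inner_max=25)
        for seed in range(3):
            data, _ = small_pair(seed=100 + seed, p=3, T=8, obs_sd=0.5)
            fit = dv.anneal_fit(data, sched=sched)
            trace = fit.bound_trace
            for (t1, b1), (t2, b2) in zip(trace, trace[1:]):
                if t1 == t2:
                    assert b2 >= b1 - 1e-8 * abs(b1)

    def test_posteriors_harden_at_termination(self):
        data, _ = small_pair(seed=4, p=4, T=20, obs_sd=0.1)
        fit = dv.anneal_fit(data)
        softness = np.minimum(fit.edges.e, 1 - fit.edges.e).max()
        assert softness < 0.05

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_nan_bound_aborts_with_diagnostic(self):
        data, _ = small_pair(seed=5, p=2, T=6)
        bad = (
            dv.ObservedSeries(data[0].values * 1e200, data[0].grid, 1),
            data[1],
        )
        with pytest.raises((FloatingPointError, np.linalg.LinAlgError)):
            dv.anneal_fit(bad)


class TestSelectAlpha0:
    def test_single_grid_point_returned(self):
        data, _ = small_pair(seed=6, p=2, T=6)
        sched = dv.AnnealSchedule(tau_min=0.5, inner_max=10)
        assert select_alpha0(data, [0.05], sched=sched, stride=10) == 0.05

    def test_total_is_sum_of_fold_residuals(self):
        data, _ = small_pair(seed=6, p=2, T=8)
        sched = dv.AnnealSchedule(tau_min=0.5, inner_max=10)
        best, table = select_alpha0(
            data, [0.01, 1.0], sched=sched, stride=3, return_table=True
        )
        totals = {}
        for row in table:
            totals[row["alpha0"]] = totals.get(row["alpha0"], 0.0) + row["r2"]
        assert best == min(totals, key=lambda a: (totals[a], a))

    def test_winning_alpha0_refit_recovers_generating_network(self):
        # near-noiseless data from a sparse network with strong
        # coefficients: the residual criterion must pick an alpha0 whose
        # refit reproduces the generating networks exactly
        data, nets = small_pair(seed=11, p=3, T=30, obs_sd=0.02,
                                coeffs=(-0.8, 0.8))
        sched = dv.AnnealSchedule(inner_max=40)
        best = select_alpha0(data, [0.01, 10.0], sched=sched, stride=14)
        fit = dv.anneal_fit(data, hyper=dv.HyperParams(alpha0=best), sched=sched)
        assert np.array_equal(fit.networks[0].edges, nets[0].edges)
        assert np.array_equal(fit.networks[1].edges, nets[1].edges)
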