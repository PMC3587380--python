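"""Core domain types and densities for the joint two-condition VAR state-space model.

The model couples two first-order vector autoregressive state-space systems
(one per experimental condition) through a shared coefficient matrix ``A``
and condition-specific binary edge indicator matrices ``E^(c)``:

    x_t^(c) = (A o E^(c)) x_{t-1}^(c) + eta_t,   eta_t ~ N(0, H),  t in the grid
    y_t^(c) = x_t^(c) + rho_t,                   rho_t ~ N(0, R),  t observed

with ``o`` the Hadamard (elementwise) product, H = diag(h), R = diag(r).
Unequally spaced observations are handled by simply omitting the observation
term at grid points without a measurement.

Priors:

* ``A_ij | h_i, F_ij ~ N(0, h_i * alpha1)`` if ``F_ij = 1`` else
  ``N(0, h_i * alpha0)`` where ``F_ij = 1 - (1 - E_ij^(1))(1 - E_ij^(2))``
  (edge present in at least one condition) and ``alpha0 < alpha1`` — a
  spike-and-slab style gate on the coefficient scale.
* ``h_i ~ IG(u0, k0)``, ``r_i ~ IG(v0, l0)`` (inverse-gamma, shape /
  inverse-scale parameterization).
* ``(E_ij^(1), E_ij^(2)) | z_ij`` takes probability ``(1/2) z_ij`` for each
  disagreeing pair and ``(1/2)(1 - z_ij)`` for each agreeing pair, and
  ``z_ij ~ Beta(zeta_i0, zeta_i1)`` — small ``z_ij`` favours networks that
  share an edge status across conditions.

The initial state ``x_1`` carries no prior of its own: the first system
term is the transition from grid point 1 to 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "TimeGrid",
    "ObservedSeries",
    "NetworkModel",
    "HyperParams",
    "PosteriorTheta",
    "EdgePosterior",
    "SmoothedMoments",
    "LatentStats",
    "AnnealSchedule",
    "indicator_F",
    "potential_prior",
    "complete_log_joint",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class TimeGrid:
    """Equally spaced system grid with a subset of observed grid points.

    Parameters
    ----------
    n_grid
        Number of grid points ``T`` (grid indices run 1..T).
    observed
        Strictly increasing grid indices carrying an observation. The last
        observation defines the grid, so ``max(observed) == n_grid`` unless
        ``final_observed`` is set False (used internally for held-out
        prediction, where the final point may be unobserved).
    interval
        Physical time per grid step (e.g. 3 hours); metadata only.
    """

    n_grid: int
    observed: tuple[int, ...]
    interval: float = 1.0
    final_observed: bool = True

    def __post_init__(self) -> None:
        obs = tuple(int(t) for t in self.observed)
        object.__setattr__(self, "observed", obs)
        if self.n_grid < 1:
            raise ValueError("n_grid must be a positive integer")
        if len(obs) == 0:
            raise ValueError("observed set must be non-empty")
        if any(b <= a for a, b in zip(obs, obs[1:])):
            raise ValueError("observed indices must be strictly increasing")
        if obs[0] < 1 or obs[-1] > self.n_grid:
            raise ValueError("observed indices must lie in 1..n_grid")
        if self.final_observed and obs[-1] != self.n_grid:
            raise ValueError("last observed index must equal n_grid")
        if not self.interval > 0:
            raise ValueError("interval must be positive")

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @classmethod
    def equal(cls, n_grid: int, interval: float = 1.0) -> "TimeGrid":
        """Fully observed grid: every point 1..n_grid carries a measurement."""
        return cls(n_grid, tuple(range(1, n_grid + 1)), interval)

    def observed_mask(self) -> np.ndarray:
        """Boolean mask of length n_grid, True where a measurement exists."""
        mask = np.zeros(self.n_grid, dtype=bool)
        mask[np.asarray(self.observed) - 1] = True
        return mask


@dataclass(frozen=True)
class ObservedSeries:
    """Expression matrix (genes x observed time points) for one condition."""

    values: np.ndarray
    grid: TimeGrid
    condition: int = 1

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-d (genes x time points) array")
        if vals.shape[1] != self.grid.n_observed:
            raise ValueError(
                f"values has {vals.shape[1]} columns but the grid has "
                f"{self.grid.n_observed} observed points"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")
        if self.condition not in (1, 2):
            raise ValueError("condition must be 1 or 2")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class NetworkModel:
    """Directed weighted network: AR coefficients plus binary edge matrix.

    ``coeff[i, j]`` is the strength of the regulation gene j -> gene i;
    ``edges[i, j] == 1`` marks the regulation as present. Diagonal entries
    (autoloops) are allowed.
    """

    coeff: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coeff, dtype=float)
        edges = np.asarray(self.edges)
        if coeff.ndim != 2 or coeff.shape[0] != coeff.shape[1]:
            raise ValueError("coeff must be a square matrix")
        if edges.shape != coeff.shape:
            raise ValueError("edges must match coeff shape")
        if not np.isin(edges, (0, 1)).all():
            raise ValueError("edges must be binary")
        object.__setattr__(self, "coeff", coeff)
        object.__setattr__(self, "edges", edges.astype(np.int8))

    @property
    def n_genes(self) -> int:
        return self.coeff.shape[0]

    def effective(self) -> np.ndarray:
        """A o E: coefficients active in this condition."""
        return self.coeff * self.edges

    @property
    def n_edges(self) -> int:
        return int(self.edges.sum())


@dataclass
class HyperParams:
    """Hyperparameters of the joint model.

    alpha0/alpha1 scale the coefficient prior variance (times h_i) for
    absent/present edges; (u0, k0) and (v0, l0) are inverse-gamma
    shape/inverse-scale pairs for the system and observation variances;
    (zeta0, zeta1) are Beta parameters of the change probability z_ij,
    scalar or one value per target gene.
    """

    alpha0: float = 0.01
    alpha1: float = 1000.0
    u0: float = 1.0
    k0: float = 1.0
    v0: float = 1.0
    l0: float = 1.0
    zeta0: float | np.ndarray = 10.0
    zeta1: float | np.ndarray = 10.0

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha1", "u0", "k0", "v0", "l0"):
            if not np.all(np.asarray(getattr(self, name)) > 0):
                raise ValueError(f"{name} must be strictly positive")
        if not np.all(np.asarray(self.zeta0) > 0) or not np.all(
            np.asarray(self.zeta1) > 0
        ):
            raise ValueError("zeta parameters must be strictly positive")
        if not self.alpha0 < self.alpha1:
            raise ValueError("alpha0 must be smaller than alpha1")

    def zeta_arrays(self, p: int) -> tuple[np.ndarray, np.ndarray]:
        z0 = np.broadcast_to(np.asarray(self.zeta0, dtype=float), (p,)).copy()
        z1 = np.broadcast_to(np.asarray(self.zeta1, dtype=float), (p,)).copy()
        return z0, z1


@dataclass
class PosteriorTheta:
    """Variational posterior over model parameters.

    Q(A_i | h_i) = N(mu_A[i], h_i * inv(prec_A[i])); Q(h_i) = IG(u[i], k[i]);
    Q(r_i) = IG(v[i], l[i]); Q(z_ij) = Beta(zeta0[i, j], zeta1[i, j]).
    ``cov_A[i]`` caches inv(prec_A[i]).
    """

    mu_A: np.ndarray        # (p, p), row i = mean of coefficient row A_i
    prec_A: np.ndarray      # (p, p, p), prec_A[i] = T_Ai (scaled precision)
    u: np.ndarray           # (p,)
    k: np.ndarray           # (p,)
    v: np.ndarray           # (p,)
    l: np.ndarray           # (p,)
    zeta0: np.ndarray       # (p, p)
    zeta1: np.ndarray       # (p, p)
    cov_A: np.ndarray = field(default=None)  # (p, p, p), inverse of prec_A

    def __post_init__(self) -> None:
        if self.cov_A is None:
            self.cov_A = np.linalg.inv(self.prec_A)
        for name in ("u", "k", "v", "l"):
            if not np.all(getattr(self, name) > 0):
                raise ValueError(f"posterior {name} must be positive")
        if not (np.all(self.zeta0 > 0) and np.all(self.zeta1 > 0)):
            raise ValueError("posterior zeta parameters must be positive")

    @property
    def n_genes(self) -> int:
        return self.mu_A.shape[0]

    def h_inv_mean(self) -> np.ndarray:
        """<1/h_i> under Q(h_i) = IG(u_i, k_i)."""
        return self.u / self.k

    def r_inv_mean(self) -> np.ndarray:
        return self.v / self.l


@dataclass
class EdgePosterior:
    """Bernoulli posteriors e_ij^(c) = Q(E_ij^(c) = 1), shape (2, p, p)."""

    e: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float)
        if e.ndim != 3 or e.shape[0] != 2 or e.shape[1] != e.shape[2]:
            raise ValueError("e must have shape (2, p, p)")
        if np.any(e < 0) or np.any(e > 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        object.__setattr__(self, "e", e)

    @property
    def n_genes(self) -> int:
        return self.e.shape[1]

    def f(self) -> np.ndarray:
        """<F_ij> = 1 - (1 - e^(1))(1 - e^(2)), probability the edge exists
        in at least one condition."""
        return indicator_F(self.e[0], self.e[1])

    def disagreement(self) -> np.ndarray:
        """<[E^(1) != E^(2)]> under independent Bernoulli posteriors."""
        e1, e2 = self.e[0], self.e[1]
        return e1 * (1.0 - e2) + e2 * (1.0 - e1)

    def networks(self, mu_A: np.ndarray) -> tuple[NetworkModel, NetworkModel]:
        """Discretize at 0.5 (edge present iff e > 0.5; ties -> absent)."""
        out = []
        for c in range(2):
            edges = (self.e[c] > 0.5).astype(np.int8)
            out.append(NetworkModel(coeff=mu_A * edges, edges=edges))
        return out[0], out[1]


@dataclass
class SmoothedMoments:
    """Smoothed Gaussian moments of the hidden trajectory for one condition.

    mean: (p, T); second[t] = <x_t x_t'>; cross[t] = <x_{t+1} x_t'>
    (indexing: cross[t] pairs grid points t+2 and t+1 in 1-based terms).
    ``logdet_precision`` is log|J| of the joint posterior precision, kept
    for entropy/lower-bound computations.
    """

    mean: np.ndarray            # (p, T)
    second: np.ndarray          # (T, p, p)
    cross: np.ndarray           # (T-1, p, p)
    logdet_precision: float = np.nan

    @property
    def n_steps(self) -> int:
        return self.mean.shape[1]


@dataclass
class LatentStats:
    """Pair of per-condition smoothed moments."""

    per_condition: tuple[SmoothedMoments, SmoothedMoments]

    def __getitem__(self, c: int) -> SmoothedMoments:
        return self.per_condition[c]


@dataclass
class AnnealSchedule:
    """Temperature schedule and inner-loop convergence control.

    tau starts at ``tau_init`` and is divided by ``cool_factor`` after each
    converged inner loop until it falls below ``tau_min``.
    """

    tau_init: float = 2.5
    cool_factor: float = 1.05
    tau_min: float = 0.01
    inner_tol: float = 1e-6
    inner_max: int = 100

    def __post_init__(self) -> None:
        if not (self.tau_init > self.tau_min > 0):
            raise ValueError("require tau_init > tau_min > 0")
        if not self.cool_factor > 1:
            raise ValueError("cool_factor must exceed 1")

    def temperatures(self) -> list[float]:
        taus = []
        tau = self.tau_init
        while tau > self.tau_min:
            taus.append(tau)
            tau /= self.cool_factor
        return taus


def indicator_F(e1, e2):
    """Probability that an edge is present in at least one condition.

    F = 1 - (1 - e1)(1 - e2); on binary inputs this is the logical OR of
    the two edge indicators. Accepts scalars or arrays in [0, 1].
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if np.any(e1 < 0) or np.any(e1 > 1) or np.any(e2 < 0) or np.any(e2 > 1):
        raise ValueError("edge probabilities must lie in [0, 1]")
    out = 1.0 - (1.0 - e1) * (1.0 - e2)
    if out.ndim == 0:
        return float(out)
    return out


def potential_prior(e1: int, e2: int, z: float) -> float:
    """Normalized prior mass of an indicator pair given change probability z.

    Returns (1/2) z when the indicators disagree and (1/2)(1 - z) when they
    agree — the unique normalization proportional to the disagreement
    potential that sums to one over the four binary configurations.
    """
    if e1 not in (0, 1) or e2 not in (0, 1):
        raise ValueError("edge indicators must be binary")
    if not 0.0 <= z <= 1.0:
        raise ValueError("z must lie in [0, 1]")
    return 0.5 * z if e1 != e2 else 0.5 * (1.0 - z)


def _log_invgamma(x: np.ndarray, shape: float, inv_scale: float) -> np.ndarray:
    """log IG(x; u, k) with density k^u / Gamma(u) * x^{-u-1} exp(-k/x)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("inverse-gamma variate must be positive")
    return (
        shape * np.log(inv_scale)
        - gammaln(shape)
        - (shape + 1.0) * np.log(x)
        - inv_scale / x
    )


def complete_log_joint(
    data: Sequence[ObservedSeries],
    X: Sequence[np.ndarray],
    A: np.ndarray,
    h: np.ndarray,
    r: np.ndarray,
    z: np.ndarray,
    E: Sequence[np.ndarray],
    hyper: HyperParams,
) -> float:
    """log P(Y, X, Theta, E): the complete-data log joint density.

    Parameters
    ----------
    data
        The two observed series (conditions 1 and 2).
    X
        Hidden trajectories, one (p, T^(c)) array per condition.
    A, h, r, z
        Parameter point: coefficient matrix (p, p), system variances (p,),
        observation variances (p,), change probabilities (p, p).
    E
        Binary edge matrices, one (p, p) array per condition.
    hyper
        Prior hyperparameters.
    """
    A = np.asarray(A, dtype=float)
    h = np.asarray(h, dtype=float)
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    p = A.shape[0]
    if np.any(h <= 0) or np.any(r <= 0):
        raise ValueError("noise variances must be strictly positive")

    total = 0.0
    for c in range(2):
        series, x = data[c], np.asarray(X[c], dtype=float)
        grid = series.grid
        if x.shape != (p, grid.n_grid):
            raise ValueError("hidden trajectory shape mismatch")
        B = A * E[c]
        # system terms: transitions 1->2, ..., (T-1)->T
        resid = x[:, 1:] - B @ x[:, :-1]
        n_trans = grid.n_grid - 1
        total += -0.5 * n_trans * (p * LOG2PI + np.log(h).sum())
        total += -0.5 * float(((resid**2) / h[:, None]).sum())
        # observation terms only at observed grid points
        obs_idx = np.asarray(grid.observed) - 1
        dy = series.values - x[:, obs_idx]
        total += -0.5 * grid.n_observed * (p * LOG2PI + np.log(r).sum())
        total += -0.5 * float(((dy**2) / r[:, None]).sum())

    # gated Gaussian prior on A_ij
    F = (1 - (1 - E[0]) * (1 - E[1])).astype(float)
    var = h[:, None] * np.where(F == 1.0, hyper.alpha1, hyper.alpha0)
    total += float((-0.5 * (LOG2PI + np.log(var)) - 0.5 * A**2 / var).sum())

    # IG priors on h_i, r_i
    total += float(_log_invgamma(h, hyper.u0, hyper.k0).sum())
    total += float(_log_invgamma(r, hyper.v0, hyper.l0).sum())

    # potential x Beta prior on (E^(1)_ij, E^(2)_ij, z_ij)
    zeta0, zeta1 = hyper.zeta_arrays(p)
    disagree = E[0] != E[1]
    mass = np.where(disagree, z, 1.0 - z)
    if np.any(mass <= 0):
        return -np.inf
    total += float(np.log(0.5 * mass).sum())
    total += float(
        (
            (zeta0[:, None] - 1.0) * np.log(z)
            + (zeta1[:, None] - 1.0) * np.log(1.0 - z)
            - betaln(zeta0, zeta1)[:, None]
        ).sum()
    )
    return total
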