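"""Synthetic benchmark generator: paired scale-free networks and VAR(1) series.

The benchmark construction mirrors the Monte-Carlo design the inference is
evaluated on: a base network G0 is a scale-free graph (100 nodes, 150
edges by default) whose edges are oriented by fair coins, root nodes
(in-degree zero) receive autoloops, and every directed edge draws an AR
coefficient uniformly from {+-0.5, ..., +-0.9}. Two condition networks
G1 and G2 keep all autoloops and a common fraction (70%) of the remaining
edges; each leftover edge goes to exactly one condition by a fair coin,
with its G0 coefficient preserved. Time series are VAR(1) trajectories
with Gaussian system noise (sd 1) plus Gaussian observation noise (sd 0.1
or 1), observed either on the full grid or on a three-block unequally
spaced schedule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import NetworkModel, ObservedSeries, TimeGrid

__all__ = [
    "BenchmarkSpec",
    "make_base_network",
    "split_conditions",
    "make_condition_networks",
    "simulate_series",
    "three_block_schedule",
    "simulate_benchmark_pair",
]

logger = logging.getLogger(__name__)

DEFAULT_COEFFS = (-0.9, -0.8, -0.7, -0.6, -0.5, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of one Monte-Carlo benchmark cell."""

    n_genes: int = 100
    n_edges: int = 150
    coeff_set: tuple[float, ...] = DEFAULT_COEFFS
    frac_common: float = 0.7
    sys_sd: float = 1.0
    obs_sd: float = 0.1
    n_timepoints: int = 50
    schedule: str = "equal"
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_common <= 1.0:
            raise ValueError("frac_common must lie in [0, 1]")
        if len(self.coeff_set) == 0 or any(c == 0 for c in self.coeff_set):
            raise ValueError("coeff_set must be non-empty and exclude 0")
        if self.schedule not in ("equal", "three_block"):
            raise ValueError("schedule must be 'equal' or 'three_block'")
        if self.n_edges < 1 or self.n_genes < 2:
            raise ValueError("need at least 2 genes and 1 edge")
        max_edges = self.n_genes * (self.n_genes - 1) // 2
        if self.n_edges > max_edges:
            raise ValueError("n_edges exceeds what an undirected simple graph allows")


def _scale_free_edges(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Undirected preferential-attachment graph with exactly m edges.

    Nodes arrive one at a time and attach to existing nodes with
    probability proportional to degree + 1; after all nodes have arrived,
    additional preferential edges are inserted until the edge count is m.
    """
    if m < n - 1:
        # attach a subset of arrivals only; still connected enough for a
        # benchmark, every node joins the degree pool
        pass
    edges: set[tuple[int, int]] = set()
    degree = np.zeros(n)
    order = list(range(n))
    # seed pair
    edges.add((0, 1))
    degree[0] += 1
    degree[1] += 1
    arrivals = order[2:]
    # one preferential edge per arrival (tree backbone), as long as budget allows
    for v in arrivals:
        if len(edges) >= m:
            break
        w = degree[:v] + 1.0
        u = int(rng.choice(v, p=w / w.sum()))
        edges.add((min(u, v), max(u, v)))
        degree[u] += 1
        degree[v] += 1
    # top up with preferential pairs until exactly m edges
    attempts = 0
    while len(edges) < m and attempts < 100 * m:
        attempts += 1
        w = degree + 1.0
        u, v = rng.choice(n, size=2, replace=False, p=w / w.sum())
        key = (min(int(u), int(v)), max(int(u), int(v)))
        if key in edges:
            continue
        edges.add(key)
        degree[key[0]] += 1
        degree[key[1]] += 1
    if len(edges) != m:
        raise RuntimeError("could not place the requested number of edges")
    return sorted(edges)


def make_base_network(spec: BenchmarkSpec, rng: np.random.Generator | None = None) -> NetworkModel:
    """Base network G0: scale-free topology, random orientation, autoloops
    on roots, coefficients from the benchmark coefficient set."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    p = spec.n_genes
    und = _scale_free_edges(p, spec.n_edges, rng)
    edges = np.zeros((p, p), dtype=np.int8)
    for u, v in und:
        if rng.random() < 0.5:
            edges[v, u] = 1      # u -> v (regulator u in column)
        else:
            edges[u, v] = 1
    # roots: nodes with no incoming regulation get an autoloop
    roots = np.flatnonzero(edges.sum(axis=1) == 0)
    edges[roots, roots] = 1
    coeff = np.where(
        edges == 1,
        rng.choice(spec.coeff_set, size=(p, p)),
        0.0,
    )
    return NetworkModel(coeff=coeff, edges=edges)


def split_conditions(
    G0: NetworkModel,
    frac_common: float,
    seed: int | np.random.Generator = 0,
) -> tuple[NetworkModel, NetworkModel]:
    """Split G0 into condition networks G1, G2.

    Autoloops are always common. A fraction ``frac_common`` of the
    non-autoloop edges is shared; each remaining edge is assigned to G1 or
    G2 by a fair coin. Coefficients are copied from G0 unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = G0.n_genes
    rows, cols = np.nonzero(G0.edges)
    off = rows != cols
    idx = np.flatnonzero(off)
    n_common = int(round(frac_common * idx.size))
    perm = rng.permutation(idx.size)
    common = set(idx[perm[:n_common]].tolist())
    e1 = np.zeros((p, p), dtype=np.int8)
    e2 = np.zeros((p, p), dtype=np.int8)
    for n, (i, j) in enumerate(zip(rows, cols)):
        if i == j or n in common:
            e1[i, j] = e2[i, j] = 1
        elif rng.random() < 0.5:
            e1[i, j] = 1
        else:
            e2[i, j] = 1
    G1 = NetworkModel(coeff=G0.coeff * e1, edges=e1)
    G2 = NetworkModel(coeff=G0.coeff * e2, edges=e2)
    return G1, G2


def make_condition_networks(
    spec: BenchmarkSpec, max_attempts: int = 100
) -> tuple[NetworkModel, NetworkModel]:
    """Draw (G1, G2) whose effective dynamics are both stable.

    The coefficient set allows unstable systems; coefficients (and, if
    needed, topology) are redrawn until both spectral radii fall below 1.
    """
    rng = np.random.default_rng(spec.seed)
    G0 = make_base_network(spec, rng)
    G1, G2 = split_conditions(G0, spec.frac_common, rng)
    for attempt in range(max_attempts):
        r1 = np.max(np.abs(np.linalg.eigvals(G1.effective())))
        r2 = np.max(np.abs(np.linalg.eigvals(G2.effective())))
        if r1 < 1.0 and r2 < 1.0:
            if attempt:
                logger.info("stable coefficients found after %d redraws", attempt)
            return G1, G2
        # keep the topology and the common/specific split, redraw coefficients
        coeff = np.where(
            G0.edges == 1, rng.choice(spec.coeff_set, size=G0.edges.shape), 0.0
        )
        G1 = NetworkModel(coeff=coeff * G1.edges, edges=G1.edges)
        G2 = NetworkModel(coeff=coeff * G2.edges, edges=G2.edges)
    raise RuntimeError(
        "no stable coefficient draw found; respecify the benchmark (fewer "
        "edges or smaller coefficients)"
    )


def three_block_schedule(n_observed: int, interval: float = 1.0) -> TimeGrid:
    """Three-block unequally spaced observation schedule.

    The grid has 8n/5 points split into blocks of 3n/5, 2n/5 and 3n/5
    (n = ``n_observed``): the first block keeps every point, the second
    keeps one of every two, the third one of every three (the kept point
    of each group is its last, so the final grid point is observed). For
    n = 25 this is the 40-point grid with 15/10/15 blocks; for n = 50 the
    80-point grid with 30/20/30 blocks.
    """
    if n_observed % 5 != 0 or n_observed < 5:
        raise ValueError("three-block schedule needs n_observed divisible by 5")
    b1 = 3 * n_observed // 5
    b2 = 2 * n_observed // 5
    b3 = 3 * n_observed // 5
    n_grid = b1 + b2 + b3
    observed = list(range(1, b1 + 1))
    observed += [b1 + 2 * g for g in range(1, b2 // 2 + 1)]
    start = b1 + b2
    observed += [start + 3 * g for g in range(1, b3 // 3 + 1)]
    return TimeGrid(n_grid=n_grid, observed=tuple(observed), interval=interval)


def simulate_series(
    G: NetworkModel,
    T: int,
    sys_sd: float,
    obs_sd: float,
    schedule: str = "equal",
    seed: int | np.random.Generator = 0,
    condition: int = 1,
    burn_in: int = 100,
) -> ObservedSeries:
    """Simulate one observed series from a condition network.

    The latent trajectory iterates x_t = (A o E) x_{t-1} + eta_t from
    x_0 = 0 through ``burn_in`` discarded steps, then through the grid of
    the requested schedule; observations add independent Gaussian noise at
    the scheduled points only.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = (
        TimeGrid.equal(T) if schedule == "equal" else three_block_schedule(T)
    )
    A = G.effective()
    p = G.n_genes
    x = np.zeros(p)
    for _ in range(burn_in):
        x = A @ x + rng.normal(0.0, sys_sd, size=p)
    latent = np.empty((p, grid.n_grid))
    for t in range(grid.n_grid):
        x = A @ x + rng.normal(0.0, sys_sd, size=p)
        latent[:, t] = x
    if not np.all(np.isfinite(latent)) or np.abs(latent).max() > 1e100:
        raise FloatingPointError(
            "trajectory diverged; the network is unstable — respecify"
        )
    obs_idx = np.asarray(grid.observed) - 1
    values = latent[:, obs_idx]
    if obs_sd > 0:
        values = values + rng.normal(0.0, obs_sd, size=values.shape)
    return ObservedSeries(values=values, grid=grid, condition=condition)


def simulate_benchmark_pair(
    spec: BenchmarkSpec,
    networks: tuple[NetworkModel, NetworkModel] | None = None,
    replicate: int = 0,
) -> tuple[tuple[ObservedSeries, ObservedSeries], tuple[NetworkModel, NetworkModel]]:
    """One replicate dataset: a series from each condition network."""
    if networks is None:
        networks = make_condition_networks(spec)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 7919, replicate])
    )
    data = tuple(
        simulate_series(
            networks[c], spec.n_timepoints, spec.sys_sd, spec.obs_sd,
            spec.schedule, rng, condition=c + 1,
        )
        for c in range(2)
    )
    return data, networks
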