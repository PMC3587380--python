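"""Reading/writing expression matrices, networks and run configuration.

Expression matrices travel as TSV with gene rows and one column per
observed time point; the header row carries the physical time stamps
(or grid indices). Estimated networks are written as edge-list TSV and as
a DOT graph using the usual three-colour convention: black for shared
regulations, red for condition-1-only, green for condition-2-only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import NetworkModel, ObservedSeries, TimeGrid

__all__ = [
    "read_expression",
    "write_expression",
    "cv_screen_genes",
    "write_networks",
    "write_network_tsv",
    "read_network_tsv",
]

logger = logging.getLogger(__name__)


def read_expression(
    path,
    interval: float = 1.0,
    condition: int = 1,
) -> ObservedSeries:
    """Read a genes x time points TSV into an :class:`ObservedSeries`.

    The header row holds physical observation times; each time maps to the
    system grid index round(time / interval) + 1, so e.g. the hour
    schedule {0, 6, 9, ..., 48} at a 3-hour interval lands on grid indices
    {1, 3, 4, ..., 17}. Two observations mapping to one grid point is a
    collision and is rejected, as are non-monotone times.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        times = np.asarray([float(c) for c in frame.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric time stamp in header: {exc}") from None
    if np.any(np.diff(times) <= 0):
        raise ValueError("observation times must be strictly increasing")
    values = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-numeric or missing cells")
    idx = np.rint(times / interval).astype(int) + 1
    if len(set(idx.tolist())) != idx.size:
        dup = [int(i) for i in idx if (idx == i).sum() > 1]
        raise ValueError(
            f"observation times collide on grid index {sorted(set(dup))} at "
            f"interval {interval}"
        )
    grid = TimeGrid(n_grid=int(idx[-1]), observed=tuple(int(i) for i in idx),
                    interval=interval)
    series = ObservedSeries(values=values, grid=grid, condition=condition)
    # attach names out-of-band; the dataclass itself stays frozen
    object.__setattr__(series, "gene_names", list(frame.index))
    return series


def write_expression(series: ObservedSeries, path, gene_names=None) -> None:
    """Write a series as TSV; columns are physical times of the observed
    grid points (grid index minus one, times the interval)."""
    times = (np.asarray(series.grid.observed) - 1) * series.grid.interval
    names = gene_names or [f"g{i}" for i in range(series.n_genes)]
    frame = pd.DataFrame(series.values, index=names, columns=[repr(float(t)) for t in times])
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def cv_screen_genes(
    matrices_1,
    matrices_2,
    n_first: int = 500,
    n_final: int = 100,
    stage2: str = "mean_abs_diff",
) -> list[int]:
    """Two-stage gene screening for the two-condition analysis.

    Stage 1 ranks genes by coefficient of variation (sd over absolute
    mean) of the pooled expression and keeps the top ``n_first``. Stage 2
    ranks the survivors by a between-condition divergence — by default the
    mean absolute difference of time-matched profiles, alternatively the
    maximal absolute log fold change (``stage2='max_fold'``) — and keeps
    the top ``n_final``. Ties (e.g. identical conditions) fall back to the
    stage-1 order.
    """
    m1 = np.asarray(matrices_1, dtype=float)
    m2 = np.asarray(matrices_2, dtype=float)
    if m1.shape[0] != m2.shape[0]:
        raise ValueError("conditions must share the gene set")
    if n_final > n_first:
        raise ValueError("n_final must not exceed n_first")
    pooled = np.concatenate([m1, m2], axis=1)
    mean = pooled.mean(axis=1)
    sd = pooled.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(np.abs(mean) > 0, sd / np.abs(mean), 0.0)
    cv[sd == 0] = 0.0  # constant genes rank last
    stage1 = np.argsort(-cv, kind="stable")[: min(n_first, cv.size)]

    k = min(m1.shape[1], m2.shape[1])
    if stage2 == "mean_abs_diff":
        score = np.abs(m1[:, :k] - m2[:, :k]).mean(axis=1)
    elif stage2 == "max_fold":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.abs(
                np.log((np.abs(m1[:, :k]) + 1e-12) / (np.abs(m2[:, :k]) + 1e-12))
            )
        score = ratio.max(axis=1)
    else:
        raise ValueError("stage2 must be 'mean_abs_diff' or 'max_fold'")
    order = sorted(range(stage1.size), key=lambda r: (-score[stage1[r]], r))
    return [int(stage1[r]) for r in order[:n_final]]


def write_network_tsv(net: NetworkModel, path, gene_names=None, e_prob=None) -> None:
    """Edge-list TSV (source regulator, target, coefficient, posterior)."""
    names = gene_names or [f"g{i}" for i in range(net.n_genes)]
    rows = []
    for i, j in zip(*np.nonzero(net.edges)):
        row = {"source": names[j], "target": names[i],
               "coefficient": net.coeff[i, j]}
        if e_prob is not None:
            row["posterior"] = e_prob[i, j]
        rows.append(row)
    cols = ["source", "target", "coefficient"] + (
        ["posterior"] if e_prob is not None else []
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_network_tsv(path, gene_names) -> NetworkModel:
    frame = pd.read_csv(path, sep="\t")
    p = len(gene_names)
    lookup = {g: i for i, g in enumerate(gene_names)}
    coeff = np.zeros((p, p))
    edges = np.zeros((p, p), dtype=np.int8)
    for _, row in frame.iterrows():
        i, j = lookup[row["target"]], lookup[row["source"]]
        edges[i, j] = 1
        coeff[i, j] = row["coefficient"]
    return NetworkModel(coeff=coeff, edges=edges)


def write_networks(fit, out_dir, gene_names=None, prefix="network") -> dict:
    """Write a fit's networks: per-condition edge lists, a combined
    annotated list (common / condition-1-only / condition-2-only), and a
    three-colour DOT graph. Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nets = fit.networks
    p = nets[0].n_genes
    names = gene_names or [f"g{i}" for i in range(p)]
    paths = {}
    for c in range(2):
        path = out_dir / f"{prefix}_condition{c + 1}.tsv"
        write_network_tsv(nets[c], path, names, e_prob=fit.edges.e[c])
        paths[f"condition{c + 1}"] = path

    e1, e2 = nets[0].edges.astype(bool), nets[1].edges.astype(bool)
    categories = [
        ("common", e1 & e2, "black"),
        ("condition1_only", e1 & ~e2, "red"),
        ("condition2_only", e2 & ~e1, "green"),
    ]
    rows = []
    dot = ["digraph network {"]
    for label, mask, colour in categories:
        for i, j in zip(*np.nonzero(mask)):
            rows.append(
                {"source": names[j], "target": names[i], "category": label,
                 "coefficient": nets[0].coeff[i, j] if label != "condition2_only"
                 else nets[1].coeff[i, j]}
            )
            dot.append(f'  "{names[j]}" -> "{names[i]}" [color={colour}];')
    dot.append("}")
    combined = out_dir / f"{prefix}_combined.tsv"
    pd.DataFrame(rows, columns=["source", "target", "category", "coefficient"]).to_csv(
        combined, sep="\t", index=False
    )
    dot_path = out_dir / f"{prefix}.dot"
    dot_path.write_text("\n".join(dot) + "\n")
    paths["combined"] = combined
    paths["dot"] = dot_path
    return paths
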