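"""Scoring of estimated networks and the Monte-Carlo benchmark driver.

Two metric families are reported, matching how differential network
estimates are usually judged:

* edge recovery — every predicted regulation (i, j, condition) counts as a
  true positive if the true network of that condition contains it, pooled
  over both conditions;
* change detection — a predicted change is an edge present in exactly one
  *estimated* network; it is a true positive only if the true networks
  contain that edge in exactly that condition. An edge that is common in
  truth but estimated in one condition only is a false positive here even
  though it is a true positive for edge recovery.

Precision is TP / (TP + FP), reported as NaN when nothing is predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annealing import AnnealSchedule, HyperParams, anneal_fit, em_fit
from .model import NetworkModel
from .simdata import BenchmarkSpec, make_condition_networks, simulate_benchmark_pair

__all__ = ["Metrics", "edge_metrics", "change_metrics", "run_benchmark"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")


def _check_pair(est, truth):
    p = truth[0].n_genes
    for net in (*est, *truth):
        if net.n_genes != p:
            raise ValueError("all networks must share the same gene set")


def edge_metrics(est, truth) -> Metrics:
    """Pooled true/false positives of predicted regulations (autoloops
    included)."""
    _check_pair(est, truth)
    tp = fp = 0
    for c in range(2):
        pred = est[c].edges.astype(bool)
        true = truth[c].edges.astype(bool)
        tp += int((pred & true).sum())
        fp += int((pred & ~true).sum())
    return Metrics(tp=tp, fp=fp)


def change_metrics(est, truth) -> Metrics:
    """True/false positives of predicted condition-specific regulations.

    Autoloops are excluded: they are common by construction in the
    benchmark, so a change on the diagonal can only ever be an artifact.
    """
    _check_pair(est, truth)
    p = truth[0].n_genes
    off = ~np.eye(p, dtype=bool)
    e1, e2 = est[0].edges.astype(bool), est[1].edges.astype(bool)
    t1, t2 = truth[0].edges.astype(bool), truth[1].edges.astype(bool)
    tp = fp = 0
    for pred_c, true_c, true_other in ((e1 & ~e2, t1, t2), (e2 & ~e1, t2, t1)):
        pred = pred_c & off
        correct = pred & true_c & ~true_other
        tp += int(correct.sum())
        fp += int((pred & ~correct).sum())
    return Metrics(tp=tp, fp=fp)


def run_benchmark(
    spec: BenchmarkSpec,
    method: str = "anneal",
    hyper: HyperParams | None = None,
    sched: AnnealSchedule | None = None,
    update_hyper: bool = True,
) -> pd.DataFrame:
    """Monte-Carlo benchmark: simulate, fit and score ``n_replicates``
    datasets from one network pair.

    Returns a tidy frame with one row per (replicate, metric family) and
    a trailing ``mean`` row per family. Failed fits are recorded and
    excluded from the means with a warning.
    """
    if method not in ("anneal", "em"):
        raise ValueError("method must be 'anneal' or 'em'")
    fit = anneal_fit if method == "anneal" else em_fit
    networks = make_condition_networks(spec)
    rows = []
    for rep in range(spec.n_replicates):
        data, _ = simulate_benchmark_pair(spec, networks=networks, replicate=rep)
        try:
            result = fit(data, hyper=hyper, sched=sched, update_hyper=update_hyper)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            logger.warning("replicate %d failed: %s", rep, exc)
            rows.append(
                {"replicate": rep, "family": "edge", "tp": np.nan, "fp": np.nan,
                 "precision": np.nan, "failed": True}
            )
            continue
        for family, metric in (
            ("edge", edge_metrics(result.networks, networks)),
            ("change", change_metrics(result.networks, networks)),
        ):
            rows.append(
                {"replicate": rep, "family": family, "tp": metric.tp,
                 "fp": metric.fp, "precision": metric.precision, "failed": False}
            )
    frame = pd.DataFrame(rows)
    ok = frame[~frame["failed"]]
    if frame["failed"].any():
        logger.warning(
            "%d replicate(s) failed and are excluded from means",
            int(frame["failed"].sum()) ,
        )
    means = (
        ok.groupby("family")[["tp", "fp", "precision"]].mean().reset_index()
    )
    means.insert(0, "replicate", "mean")
    means["failed"] = False
    return pd.concat([frame, means], ignore_index=True)


def benchmark_summary(frame: pd.DataFrame) -> dict:
    """Machine-readable summary (the per-family mean rows) as a dict."""
    out = {}
    means = frame[frame["replicate"] == "mean"]
    for _, row in means.iterrows():
        out[row["family"]] = {
            "tp": float(row["tp"]),
            "fp": float(row["fp"]),
            "precision": float(row["precision"]),
        }
    return out
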