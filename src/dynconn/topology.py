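"""Per-window graph topology and its temporal variability.

Each windowed connectivity matrix is binarized at a range of sparsity
levels (keeping the strongest edges by |z|), per-node efficiency metrics
are computed on each binary graph, aggregated across sparsity by the area
under the curve (AUC), and summarized over windows by the coefficient of
variation (CV = SD/mean) — the temporal variability of network topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dfc import DynamicConnectome
from .states import upper_tri_vec

__all__ = [
    "TopologyConfig",
    "TopologyVariability",
    "default_sparsity_grid",
    "binarize_at_sparsity",
    "hop_distances",
    "nodal_efficiency",
    "local_efficiency",
    "auc_over_sparsity",
    "temporal_cv",
    "topology_variability",
]

METRICS = ("nodal_efficiency", "local_efficiency")


def default_sparsity_grid() -> np.ndarray:
    """Connectome-standard sparsity range 0.10-0.34 in steps of 0.01."""
    return np.round(np.arange(0.10, 0.3401, 0.01), 2)


@dataclass
class TopologyConfig:
    """Binarization and variability parameters."""

    sparsity_grid: np.ndarray = field(default_factory=default_sparsity_grid)
    metrics: tuple[str, ...] = METRICS
    cv_ddof: int = 1
    absolute: bool = True  # rank edges by |z|; False ranks signed z

    def __post_init__(self) -> None:
        grid = np.asarray(self.sparsity_grid, dtype=float)
        if grid.size == 0 or (np.diff(grid) <= 0).any():
            raise ValueError("sparsity_grid must be nonempty, strictly ascending")
        if grid[0] <= 0 or grid[-1] >= 1:
            raise ValueError("sparsity values must lie in (0, 1)")
        self.sparsity_grid = grid
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if self.cv_ddof not in (0, 1):
            raise ValueError("cv_ddof must be 0 or 1")


@dataclass
class TopologyVariability:
    """Temporal variability of AUC-aggregated efficiency metrics.

    ``cv`` maps metric name to a subject x node DataFrame; ``auc_series``
    (kept when requested) maps metric to per-subject (W, P) arrays.
    """

    cv: dict[str, pd.DataFrame]
    auc_series: dict[str, dict[str, np.ndarray]]
    sparsity_grid: np.ndarray


def binarize_at_sparsity(
    z_matrix: np.ndarray, sparsity: float, absolute: bool = True
) -> np.ndarray:
    """Keep the floor(s * E) strongest edges as an undirected binary graph.

    Edges are ranked by |z| (or signed z with ``absolute=False``); ties are
    broken by upper-triangle (i, j) index order.  An all-zero matrix is
    degenerate — the retained edge set is then determined by the tie rule
    alone, and a warning is raised.
    """
    if not (0 < sparsity < 1):
        raise ValueError("sparsity must lie in (0, 1)")
    z_matrix = np.asarray(z_matrix, dtype=float)
    P = z_matrix.shape[0]
    vec = upper_tri_vec(z_matrix)
    if not vec.any():
        warnings.warn("all-zero connectivity matrix; edges chosen by tie rule",
                      stacklevel=2)
    strength = np.abs(vec) if absolute else vec
    m = int(np.floor(sparsity * vec.shape[0]))
    keep = np.argsort(-strength, kind="stable")[:m]
    adj = np.zeros((P, P), dtype=bool)
    iu = np.triu_indices(P, k=1)
    adj[iu[0][keep], iu[1][keep]] = True
    return adj | adj.T


def hop_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths by frontier expansion.

    Simultaneous BFS from every source via boolean matrix products;
    unreachable pairs get +inf, the diagonal is 0.
    """
    adj_u8 = np.asarray(adj, dtype=bool).astype(np.uint8)
    P = adj_u8.shape[0]
    dist = np.full((P, P), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(P, dtype=bool)
    frontier = np.eye(P, dtype=np.uint8)
    d = 0
    while frontier.any() and d < P:
        d += 1
        frontier_b = ((frontier @ adj_u8) > 0) & ~reached
        dist[frontier_b] = d
        reached |= frontier_b
        frontier = frontier_b.astype(np.uint8)
    return dist


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    """Per-node efficiency: mean inverse shortest-path length to all others.

    ``E_nod(i) = (1/(P-1)) * sum_{j != i} 1/d(i, j)``; unreachable pairs
    contribute 0.  Lies in [0, 1]; an isolated node scores 0 and a node in
    a complete graph scores 1.
    """
    adj = np.asarray(adj, dtype=bool)
    P = adj.shape[0]
    if P < 2:
        return np.zeros(P)
    dist = hop_distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (P - 1)


def local_efficiency(adj: np.ndarray) -> np.ndarray:
    """Per-node local efficiency: global efficiency among its neighbors.

    The subgraph induced by node i's direct neighbors (i itself removed)
    is extracted and ``E_loc(i)`` is the mean inverse distance over
    ordered neighbor pairs within that subgraph.  Nodes with fewer than
    two neighbors score 0.
    """
    adj = np.asarray(adj, dtype=bool)
    P = adj.shape[0]
    out = np.zeros(P)
    for i in range(P):
        nbrs = np.flatnonzero(adj[i])
        m = nbrs.size
        if m < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        dist = hop_distances(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / dist
        np.fill_diagonal(inv, 0.0)
        out[i] = inv.sum() / (m * (m - 1))
    return out


_METRIC_FUNCS = {
    "nodal_efficiency": nodal_efficiency,
    "local_efficiency": local_efficiency,
}


def auc_over_sparsity(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Trapezoidal area under a metric curve across sparsity levels."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape[-1] != grid.shape[0]:
        raise ValueError("values and sparsity grid lengths differ")
    return np.trapezoid(values, grid, axis=-1)


def temporal_cv(series: np.ndarray, ddof: int = 1) -> float:
    """Coefficient of variation SD/mean of a time series of metric values.

    Undefined (NaN, with a warning) when the mean is nonpositive.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if series.size == 1 and ddof == 1:
        raise ValueError("length-1 series has no sample SD")
    mean = series.mean()
    if mean <= 0:
        warnings.warn("nonpositive mean; CV undefined", stacklevel=2)
        return float("nan")
    return float(series.std(ddof=ddof) / mean)


def window_efficiency_auc(
    z_stack: np.ndarray, cfg: TopologyConfig
) -> dict[str, np.ndarray]:
    """AUC-aggregated per-node efficiency for every window of a stack.

    Returns metric name -> (W, P) array: each window is binarized at every
    sparsity level, per-node metrics are computed and integrated across
    the grid.
    """
    W, P, _ = z_stack.shape
    S = cfg.sparsity_grid.shape[0]
    out = {m: np.empty((W, P)) for m in cfg.metrics}
    vals = {m: np.empty((S, P)) for m in cfg.metrics}
    for wi in range(W):
        for si, s in enumerate(cfg.sparsity_grid):
            adj = binarize_at_sparsity(z_stack[wi], s, cfg.absolute)
            for m in cfg.metrics:
                vals[m][si] = _METRIC_FUNCS[m](adj)
        for m in cfg.metrics:
            out[m][wi] = auc_over_sparsity(vals[m].T, cfg.sparsity_grid)
    return out


def topology_variability(
    dcs: Sequence[DynamicConnectome],
    cfg: TopologyConfig = None,
    keep_series: bool = False,
) -> TopologyVariability:
    """Temporal CV of AUC-aggregated efficiency metrics per subject/node."""
    if cfg is None:
        cfg = TopologyConfig()
    cv_rows: dict[str, list] = {m: [] for m in cfg.metrics}
    series: dict[str, dict[str, np.ndarray]] = {m: {} for m in cfg.metrics}
    index = []
    for dc in dcs:
        aucs = window_efficiency_auc(dc.z_stack, cfg)
        index.append(dc.subject_id)
        for m in cfg.metrics:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv_rows[m].append([
                    temporal_cv(aucs[m][:, p], cfg.cv_ddof)
                    for p in range(dc.n_nodes)
                ])
            if keep_series:
                series[m][dc.subject_id] = aucs[m]
    node_cols = list(range(1, dcs[0].n_nodes + 1))
    cv = {
        m: pd.DataFrame(cv_rows[m], index=index, columns=node_cols)
        for m in cfg.metrics
    }
    return TopologyVariability(cv=cv, auc_series=series,
                               sparsity_grid=cfg.sparsity_grid)
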