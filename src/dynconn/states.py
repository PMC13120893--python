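"""Recurring connectivity states and their temporal dynamics.

Windowed connectivity matrices (as upper-triangle z-vectors) are clustered
with L1 (Manhattan) k-means: exemplar windows at local maxima of the
connectivity variance are pooled across subjects, the cluster number is
chosen by a knee (elbow) criterion on the normalized within-cluster
dispersion over a range of k, and every window of every subject is then
assigned to its nearest centroid.  Each subject's resulting state sequence yields the
classic temporal metrics: fractional window (FW, % of windows per state),
mean dwell time (MDT, mean run length per state, in windows) and number
of transitions (NT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .dfc import DynamicConnectome

__all__ = [
    "ClusterConfig",
    "StateModel",
    "StateTemporalMetrics",
    "upper_tri_vec",
    "vec_to_matrix",
    "subsample_variance_peaks",
    "kmeans_l1",
    "cluster_validity_index",
    "elbow_select",
    "assign_all_windows",
    "temporal_metrics",
    "cohort_temporal_metrics",
    "fit_state_model",
    "centroid_contrasts",
    "top_edges",
    "group_centroids",
    "match_centroids",
    "robustness_over_k",
]


def upper_tri_vec(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle (k=1) vector of a symmetric matrix, row-major order."""
    mat = np.asarray(mat)
    iu = np.triu_indices(mat.shape[-1], k=1)
    return mat[..., iu[0], iu[1]]


def vec_to_matrix(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`upper_tri_vec`: symmetric matrix, zero diagonal."""
    mat = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    mat[iu] = vec
    return mat + mat.T


@dataclass
class ClusterConfig:
    """L1 k-means and model-selection parameters."""

    k_range: tuple[int, int] = (2, 10)
    n_replicates: int = 100
    seed: int = 0
    max_iter: int = 300
    refine_assignment: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.k_range
        if lo < 1 or hi < lo:
            raise ValueError("k_range must be a nonempty integer interval")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def ks(self) -> list[int]:
        return list(range(self.k_range[0], self.k_range[1] + 1))


@dataclass
class StateModel:
    """Fitted cluster model plus per-subject state sequences."""

    k: int
    centroids: np.ndarray  # (k, P*(P-1)/2)
    n_nodes: int
    state_vectors: dict[str, np.ndarray]  # subject_id -> labels in 1..k
    subsample_index: dict[str, np.ndarray]
    validity_curve: dict[int, float]
    inertia: float

    def centroid_matrix(self, state: int) -> np.ndarray:
        return vec_to_matrix(self.centroids[state - 1], self.n_nodes)


@dataclass
class StateTemporalMetrics:
    """Per-subject temporal metrics of the state sequence.

    ``fw`` and ``mdt`` are subject x state frames (states as columns 1..k);
    MDT is NaN for states a subject never visits.  ``nt`` is a per-subject
    series.  ``mdt_seconds`` converts dwell from windows to seconds given
    the repetition time and window step.
    """

    fw: pd.DataFrame
    mdt: pd.DataFrame
    nt: pd.Series

    def mdt_seconds(self, tr_seconds: float = 0.72, step: int = 1) -> pd.DataFrame:
        return self.mdt * tr_seconds * step


def subsample_variance_peaks(dc: DynamicConnectome) -> np.ndarray:
    """Indices of windows at local maxima of connectivity variance.

    The variance of the upper-triangle z-values is computed per window and
    strict interior local maxima are returned (a plateau that is a local
    maximum contributes its first index).  If no interior peak exists, all
    windows are returned with a warning.
    """
    var = upper_tri_vec(dc.z_stack).var(axis=1)
    W = var.shape[0]
    if W < 3:
        warnings.warn("fewer than 3 windows; returning all", stacklevel=2)
        return np.arange(W)
    # collapse runs of equal values so plateaus count once
    change = np.flatnonzero(np.diff(var) != 0) + 1
    run_starts = np.r_[0, change]
    run_vals = var[run_starts]
    peaks = []
    for ri in range(1, len(run_vals) - 1):
        if run_vals[ri] > run_vals[ri - 1] and run_vals[ri] > run_vals[ri + 1]:
            peaks.append(run_starts[ri])
    if not peaks:
        warnings.warn("no interior variance peaks; returning all windows",
                      stacklevel=2)
        return np.arange(W)
    return np.asarray(peaks, dtype=np.int64)


def _l1_assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = cdist(X, centroids, metric="cityblock")
    labels = np.argmin(d, axis=1)  # argmin resolves ties at the lowest index
    return labels, d[np.arange(len(X)), labels]


def _lloyd_l1(
    X: np.ndarray, init: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    centroids = init.copy()
    k = centroids.shape[0]
    labels = np.full(len(X), -1)
    for _ in range(max_iter):
        new_labels, dists = _l1_assign(X, centroids)
        # repair empty clusters: move them to the worst-fit points
        for c in range(k):
            if not (new_labels == c).any():
                far = int(np.argmax(dists))
                centroids[c] = X[far]
                new_labels[far] = c
                dists[far] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = np.median(X[labels == c], axis=0)
    labels, dists = _l1_assign(X, centroids)
    return centroids, labels, float(dists.sum())


def kmeans_l1(
    X: np.ndarray,
    k: int,
    n_replicates: int = 100,
    seed: int = 0,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """L1 (Manhattan) k-means: median update, best of random restarts.

    Assignment is to the nearest centroid in L1 distance with ties broken
    toward the lowest state index; the centroid update is the
    component-wise median (the L1 minimizer).  The best of
    ``n_replicates`` random initializations by total L1 inertia is
    returned as ``(centroids, labels, inertia)``.  Deterministic given
    ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < k:
        raise ValueError(f"{n} exemplars cannot support k={k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_replicates):
        init = X[rng.choice(n, size=k, replace=False)]
        centroids, labels, inertia = _lloyd_l1(X, init, max_iter)
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia)
    return best


def cluster_validity_index(
    X: np.ndarray, centroids: np.ndarray, labels: np.ndarray
) -> float:
    """Normalized within-cluster dispersion used for elbow selection.

    Mean L1 distance of points to their assigned centroid, divided by the
    total dispersion (mean L1 distance to the global component-wise
    median).  Dimensionless, decreasing in k; the curve flattens past the
    true cluster number, producing a knee there.
    """
    within = float(np.mean(np.abs(X - centroids[labels]).sum(axis=1)))
    total = float(np.mean(np.abs(X - np.median(X, axis=0)).sum(axis=1)))
    if total == 0:
        return 0.0
    return within / total


def elbow_select(validity_curve: dict[int, float]) -> int:
    """Pick the cluster number at the elbow (knee) of the validity curve.

    The elbow is the k whose CVI value lies farthest below the chord
    joining the curve's endpoints — the standard knee rule, invariant to
    the curve's scale and offset.  Ties go to the smaller k; a flat or
    linear curve has no knee and falls back to the smallest k with a
    warning.
    """
    ks = sorted(validity_curve)
    if len(ks) < 3:
        raise ValueError("need at least 3 k values for elbow selection")
    cvi = np.array([validity_curve[k] for k in ks], dtype=float)
    karr = np.array(ks, dtype=float)
    chord = cvi[0] + (cvi[-1] - cvi[0]) * (karr - karr[0]) / (karr[-1] - karr[0])
    gap = chord - cvi
    if np.nanmax(gap) <= 1e-12:
        warnings.warn("validity curve has no knee; using smallest k",
                      stacklevel=2)
        return ks[0]
    return ks[int(np.nanargmax(gap))]


def assign_all_windows(
    dcs: Sequence[DynamicConnectome], centroids: np.ndarray
) -> dict[str, np.ndarray]:
    """Assign every window of every subject to its nearest centroid (L1).

    A single assignment pass with fixed centroids; labels are 1-based.
    """
    out = {}
    for dc in dcs:
        X = upper_tri_vec(dc.z_stack)
        labels, _ = _l1_assign(X, centroids)
        out[dc.subject_id] = labels + 1
    return out


def temporal_metrics(state_vector: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, int]:
    """FW (%), MDT (windows; NaN if unvisited) and NT for one sequence."""
    s = np.asarray(state_vector, dtype=np.int64)
    if s.size == 0:
        raise ValueError("empty state vector")
    if s.min() < 1 or s.max() > k:
        raise ValueError("state labels must lie in 1..k")
    W = s.size
    fw = np.array([100.0 * np.count_nonzero(s == st) / W for st in range(1, k + 1)])
    boundaries = np.flatnonzero(np.diff(s)) + 1
    run_starts = np.r_[0, boundaries]
    run_ends = np.r_[boundaries, W]
    run_states = s[run_starts]
    run_lengths = run_ends - run_starts
    mdt = np.full(k, np.nan)
    for st in range(1, k + 1):
        mask = run_states == st
        if mask.any():
            mdt[st - 1] = run_lengths[mask].mean()
    nt = len(run_starts) - 1
    return fw, mdt, nt


def cohort_temporal_metrics(
    state_vectors: dict[str, np.ndarray], k: int
) -> StateTemporalMetrics:
    """Temporal metrics for every subject, as subject x state frames."""
    fw_rows, mdt_rows, nt_vals, index = [], [], [], []
    for sid, vec in state_vectors.items():
        fw, mdt, nt = temporal_metrics(vec, k)
        fw_rows.append(fw)
        mdt_rows.append(mdt)
        nt_vals.append(nt)
        index.append(sid)
    cols = list(range(1, k + 1))
    return StateTemporalMetrics(
        fw=pd.DataFrame(fw_rows, index=index, columns=cols),
        mdt=pd.DataFrame(mdt_rows, index=index, columns=cols),
        nt=pd.Series(nt_vals, index=index, name="nt"),
    )


def fit_state_model(
    dcs: Sequence[DynamicConnectome],
    cfg: ClusterConfig = None,
    k_fixed: Optional[int] = None,
) -> StateModel:
    """Full state identification: subsample, cluster, select k, assign.

    Exemplar windows (variance peaks) from all subjects are pooled and
    clustered for each k in ``cfg.k_range``; the elbow of the validity
    curve fixes k unless ``k_fixed`` is given.  The winning exemplar
    centroids then label every window of every subject in one assignment
    pass (optionally with further Lloyd refinement on the full data).
    """
    if cfg is None:
        cfg = ClusterConfig()
    subsample = {dc.subject_id: subsample_variance_peaks(dc) for dc in dcs}
    X = np.vstack([
        upper_tri_vec(dc.z_stack[subsample[dc.subject_id]]) for dc in dcs
    ])
    fits: dict[int, tuple] = {}
    validity: dict[int, float] = {}
    ks = [k_fixed] if k_fixed is not None else cfg.ks
    for k in ks:
        seed_k = np.random.SeedSequence([cfg.seed, k]).generate_state(1)[0]
        centroids, labels, inertia = kmeans_l1(
            X, k, cfg.n_replicates, seed=seed_k, max_iter=cfg.max_iter
        )
        fits[k] = (centroids, labels, inertia)
        validity[k] = cluster_validity_index(X, centroids, labels)
    k_star = k_fixed if k_fixed is not None else elbow_select(validity)
    centroids, _, inertia = fits[k_star]
    if cfg.refine_assignment:
        X_all = np.vstack([upper_tri_vec(dc.z_stack) for dc in dcs])
        centroids, _, inertia = _lloyd_l1(X_all, centroids, cfg.max_iter)
    state_vectors = assign_all_windows(dcs, centroids)
    return StateModel(
        k=k_star,
        centroids=centroids,
        n_nodes=dcs[0].n_nodes,
        state_vectors=state_vectors,
        subsample_index=subsample,
        validity_curve=validity,
        inertia=inertia,
    )


def centroid_contrasts(model: StateModel) -> tuple[dict, pd.DataFrame]:
    """Pairwise centroid differences and Pearson pattern similarity."""
    k = model.k
    if k < 2:
        raise ValueError("need at least 2 states")
    diffs = {}
    sim = np.eye(k)
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            diffs[(a + 1, b + 1)] = vec_to_matrix(
                model.centroids[a] - model.centroids[b], model.n_nodes
            )
            sim[a, b] = np.corrcoef(model.centroids[a], model.centroids[b])[0, 1]
    labels = list(range(1, k + 1))
    return diffs, pd.DataFrame(sim, index=labels, columns=labels)


def top_edges(centroid: np.ndarray, fraction: float, n_nodes: int) -> pd.DataFrame:
    """Strongest edges of a centroid by |z|, with sign.

    Returns the top ``ceil(fraction * E)`` edges as a frame with columns
    ``node_i, node_j, z`` (1-based node indices); ties keep (i, j) order.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    centroid = np.asarray(centroid, dtype=float)
    iu = np.triu_indices(n_nodes, k=1)
    if centroid.shape[0] != iu[0].shape[0]:
        raise ValueError("centroid length does not match n_nodes")
    n_top = int(np.ceil(fraction * centroid.shape[0]))
    order = np.argsort(-np.abs(centroid), kind="stable")[:n_top]
    return pd.DataFrame({
        "node_i": iu[0][order] + 1,
        "node_j": iu[1][order] + 1,
        "z": centroid[order],
    })


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    return A @ B.T


def icc_2_1(ratings: np.ndarray) -> float:
    """Two-way random, absolute-agreement, single-measure ICC(2,1).

    ``ratings`` is targets x raters (here: edges x groups).
    """
    Y = np.asarray(ratings, dtype=float)
    n, k = Y.shape
    mean_t = Y.mean(axis=1, keepdims=True)
    mean_r = Y.mean(axis=0, keepdims=True)
    grand = Y.mean()
    ms_r = k * ((mean_t - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((mean_r - grand) ** 2).sum() / (k - 1)
    sse = ((Y - mean_t - mean_r + grand) ** 2).sum()
    ms_e = sse / ((n - 1) * (k - 1))
    return float(
        (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
    )


def group_centroids(
    dcs: Sequence[DynamicConnectome],
    state_vectors: dict[str, np.ndarray],
    groups: dict[str, str],
    k: int,
    similarity: str = "pearson",
) -> tuple[dict[str, np.ndarray], dict[int, pd.DataFrame]]:
    """Per-group state centroids and their cross-group pattern agreement.

    Each subject's centroid for a state is the mean of that subject's
    windows assigned to the state (subjects that never visit a state are
    excluded from that state's average); the group centroid averages over
    the group's subjects.  Agreement across groups is Pearson pattern
    correlation by default, or ICC(2,1) with ``similarity='icc'``.
    """
    group_names = sorted(set(groups.values()))
    subj_cent: dict[str, np.ndarray] = {}
    for dc in dcs:
        X = upper_tri_vec(dc.z_stack)
        labels = state_vectors[dc.subject_id]
        cent = np.full((k, X.shape[1]), np.nan)
        for st in range(1, k + 1):
            mask = labels == st
            if mask.any():
                cent[st - 1] = X[mask].mean(axis=0)
        subj_cent[dc.subject_id] = cent
    out_cent: dict[str, np.ndarray] = {}
    for g in group_names:
        members = [subj_cent[sid] for sid, gg in groups.items() if gg == g
                   and sid in subj_cent]
        if not members:
            raise ValueError(f"group {g!r} has no subjects")
        stack = np.stack(members)  # (n_subj, k, E)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out_cent[g] = np.nanmean(stack, axis=0)
    agreement: dict[int, pd.DataFrame] = {}
    for st in range(1, k + 1):
        mat = np.eye(len(group_names))
        for i, gi in enumerate(group_names):
            for j, gj in enumerate(group_names):
                if i >= j:
                    continue
                a, b = out_cent[gi][st - 1], out_cent[gj][st - 1]
                if similarity == "icc":
                    val = icc_2_1(np.column_stack([a, b]))
                else:
                    val = float(np.corrcoef(a, b)[0, 1])
                mat[i, j] = mat[j, i] = val
        agreement[st] = pd.DataFrame(mat, index=group_names, columns=group_names)
    return out_cent, agreement


def match_centroids(
    centroids: np.ndarray, reference: np.ndarray
) -> pd.DataFrame:
    """Best-match Pearson similarity of each reference pattern to a model.

    Returns one row per reference pattern with the index and correlation
    of its best-matching centroid.
    """
    sim = _pearson_rows(np.asarray(reference, float).copy(),
                        np.asarray(centroids, float).copy())
    best = np.argmax(sim, axis=1)
    return pd.DataFrame({
        "reference": np.arange(1, len(reference) + 1),
        "best_centroid": best + 1,
        "similarity": sim[np.arange(len(reference)), best],
    })


def robustness_over_k(
    dcs: Sequence[DynamicConnectome],
    cfg: ClusterConfig,
    k_list: Sequence[int],
    primary: StateModel,
) -> dict[int, dict]:
    """Re-fit the state model at alternative cluster numbers.

    For each k the clustering, assignment and temporal metrics are fully
    re-run (same seed policy as the primary fit) and each primary centroid
    is matched to its most similar alternative centroid.
    """
    out = {}
    for k in k_list:
        model = fit_state_model(dcs, cfg, k_fixed=k)
        metrics = cohort_temporal_metrics(model.state_vectors, model.k)
        out[k] = {
            "model": model,
            "metrics": metrics,
            "primary_match": match_centroids(model.centroids, primary.centroids),
        }
    return out
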