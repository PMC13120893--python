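"""Sliding-window dynamic functional connectivity estimation.

For each subject a tapered window (rectangle convolved with a Gaussian)
slides along the cleaned IC time courses.  Within each window a weighted
sample covariance is formed and a sparse inverse covariance (precision)
matrix is estimated by the graphical lasso; the L1 penalty lambda is
selected once per subject by cross-validation on the full time series.
The per-window precision is inverted back to a covariance, normalized to
correlations and Fisher r-to-z transformed, yielding a W x P x P stack of
z-scored connectivity matrices per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import gaussian as gaussian_window
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "TaperSpec",
    "WindowEstimatorConfig",
    "DynamicConnectome",
    "build_taper",
    "count_windows",
    "weighted_covariance",
    "glasso_precision",
    "select_lambda",
    "precision_to_z",
    "compute_dynamic_connectome",
]

#: default log-spaced penalty grid for per-subject cross-validation
DEFAULT_LAMBDA_GRID = tuple(np.logspace(np.log10(0.03), 0.0, 10))

_CLIP = 1.0 - 1e-7  # correlation clipping bound before atanh


@dataclass(frozen=True)
class TaperSpec:
    """Tapered sliding-window weights (rectangle * Gaussian)."""

    window_length: int
    gaussian_sigma: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.window_length,):
            raise ValueError("weights must have length window_length")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)


@dataclass
class WindowEstimatorConfig:
    """Window stepping and penalty-selection parameters."""

    step: int = 1
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    cv_folds: int = 5
    lambda_selected: float | None = None
    glasso_tol: float = 1e-4
    glasso_max_iter: int = 200
    partial_correlation: bool = False

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        grid = tuple(float(v) for v in self.lambda_grid)
        if not grid or any(v <= 0 for v in grid):
            raise ValueError("lambda_grid must hold positive values")
        if list(grid) != sorted(grid):
            raise ValueError("lambda_grid must be sorted ascending")
        self.lambda_grid = grid
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class DynamicConnectome:
    """Per-subject stack of windowed Fisher-z connectivity matrices.

    ``z_stack`` has shape (W, P, P) with symmetric slices and zero
    diagonal; ``window_starts`` gives each window's first time index.
    """

    subject_id: str
    z_stack: np.ndarray
    window_starts: np.ndarray
    window_length: int
    lambda_selected: float

    @property
    def n_windows(self) -> int:
        return self.z_stack.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.z_stack.shape[1]


def build_taper(window_length: int, gaussian_sigma: float) -> TaperSpec:
    """Convolve a rectangle with a Gaussian to obtain window weights.

    The Gaussian kernel is evaluated on an integer grid spanning +/- 4
    sigma (rounded up); the full discrete convolution is cropped to its
    central ``window_length`` samples and renormalized to sum 1.  As sigma
    goes to 0 the taper degenerates to the uniform rectangle.
    """
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if gaussian_sigma <= 0:
        raise ValueError("gaussian_sigma must be positive")
    half = int(np.ceil(4.0 * gaussian_sigma))
    kernel = gaussian_window(2 * half + 1, std=gaussian_sigma)
    rect = np.ones(window_length)
    full = np.convolve(rect, kernel, mode="full")
    centre = (len(full) - window_length) // 2
    w = full[centre:centre + window_length]
    return TaperSpec(window_length, gaussian_sigma, w / w.sum())


def count_windows(t_effective: int, window_length: int, step: int = 1) -> int:
    """Number of sliding-window positions: floor((T - L)/step) + 1."""
    if t_effective < window_length:
        raise ValueError(
            f"need at least {window_length} time points, got {t_effective}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    return (t_effective - window_length) // step + 1


def weighted_covariance(segment: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Taper-weighted sample covariance of a P x L segment.

    S = sum_t w_t (x_t - mu_w)(x_t - mu_w)^T with mu_w the weighted mean;
    with uniform weights this equals the population-style covariance.
    Zero-variance nodes within the window are rejected.
    """
    segment = np.asarray(segment, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if segment.shape[1] != weights.shape[0]:
        raise ValueError("segment length does not match weights")
    mu = segment @ weights
    centred = segment - mu[:, None]
    S = (centred * weights) @ centred.T
    zero_var = np.diag(S) <= 0
    if zero_var.any():
        raise ValueError(
            f"zero-variance node(s) in window: {np.flatnonzero(zero_var).tolist()}"
        )
    return 0.5 * (S + S.T)


def glasso_precision(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> np.ndarray:
    """L1-penalized precision estimate (graphical lasso).

    Maximizes ``log det Theta - tr(S Theta) - lam * sum_offdiag |Theta_ij|``
    over positive-definite Theta.  ``lam = 0`` reduces to the direct matrix
    inverse; a penalty at least as large as the largest absolute
    off-diagonal covariance forces a diagonal precision.

    Convergence policy: a slightly negative reported dual gap is a
    rounding artifact of an already-converged solution and is accepted.
    On rare strongly-correlated windows the coordinate-descent iteration
    cycles (the gap dips below tolerance and then diverges); such windows
    are retried with the LARS solver and with a 10x looser stopping
    tolerance — a gap below 10*tol is still a tight solution for the
    Fisher-z estimates downstream.  Only failure of the whole ladder
    raises ``RuntimeError``.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    attempts = [(tol, "cd"), (tol, "lars"),
                (10.0 * tol, "cd"), (10.0 * tol, "lars")]
    failures: list[str] = []
    for attempt_tol, mode in attempts:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                _, precision = graphical_lasso(S, alpha=lam, tol=attempt_tol,
                                               max_iter=max_iter, mode=mode)
            except FloatingPointError as exc:
                # a solver crash (e.g. LARS declaring the system non-SPD)
                # fails this rung only; the remaining rungs still run
                failures.append(f"{mode}@{attempt_tol:g}: {exc}")
                continue
        # only the outer solver's dual-gap warning signals non-convergence;
        # the inner elementwise Lasso may warn transiently on early
        # iterations while the outer objective still converges
        gaps = [_parse_dual_gap(str(w.message)) for w in caught
                if issubclass(w.category, ConvergenceWarning)
                and "graphical_lasso" in str(w.message)]
        if all(g is not None and g <= 10.0 * attempt_tol for g in gaps):
            return 0.5 * (precision + precision.T)
        failures.append(f"{mode}@{attempt_tol:g}: dual gaps {gaps}")
    raise RuntimeError(
        f"graphical lasso did not converge in {max_iter} iterations: "
        + "; ".join(failures)
    )


def _parse_dual_gap(message: str) -> float | None:
    import re

    m = re.search(r"dual gap: ([-+0-9.eE]+)", message)
    return float(m.group(1)) if m else None


def _contiguous_folds(n: int, folds: int) -> list[np.ndarray]:
    bounds = np.linspace(0, n, folds + 1).astype(int)
    return [np.arange(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def select_lambda(
    data: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    cv_folds: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """Select the glasso penalty by contiguous-block cross-validation.

    The subject's full (unwindowed) P x T series is split into ``cv_folds``
    contiguous temporal blocks, respecting autocorrelation.  For each
    candidate penalty, the precision is fit on the training covariance and
    scored by held-out Gaussian log-likelihood
    ``log det Theta - tr(S_test Theta)``; the penalty maximizing the mean
    held-out score is returned (ties go to the smaller penalty).
    """
    data = np.asarray(data, dtype=float)
    P, T = data.shape
    if T < cv_folds:
        raise ValueError("fewer time points than folds")
    grid = [float(v) for v in lambda_grid]
    if not grid:
        raise ValueError("empty lambda grid")
    if len(grid) == 1:
        return grid[0]
    folds = _contiguous_folds(T, cv_folds)
    all_idx = np.arange(T)
    scores = np.zeros(len(grid))
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        S_train = _standardize(np.cov(data[:, train_idx], bias=True))
        S_test = _standardize(np.cov(data[:, test_idx], bias=True))
        for gi, lam in enumerate(grid):
            theta = glasso_precision(S_train, lam, tol=tol, max_iter=max_iter)
            sign, logdet = np.linalg.slogdet(theta)
            if sign <= 0:
                scores[gi] += -np.inf
                continue
            scores[gi] += logdet - np.trace(S_test @ theta)
    best = int(np.argmax(scores))  # argmax takes the first (smallest) maximizer
    return grid[best]


def _standardize(S: np.ndarray) -> np.ndarray:
    """Rescale a covariance to a correlation matrix (unit diagonal).

    The lasso penalty is not scale-invariant; solving on the correlation
    scale penalizes every edge equally and markedly improves the
    coordinate-descent conditioning.  The Fisher-z output is unaffected in
    the unpenalized limit (correlations are scale-free).
    """
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def precision_to_z(theta: np.ndarray, partial_correlation: bool = False) -> np.ndarray:
    """Convert a precision matrix to Fisher-z correlations.

    Default: invert to a covariance, normalize to correlations, clip
    magnitudes below 1 and apply atanh; the diagonal is set to zero.  With
    ``partial_correlation=True`` the z-values are instead computed from the
    negative scaled precision entries (partial correlations).
    """
    theta = np.asarray(theta, dtype=float)
    w = np.linalg.eigvalsh(theta)
    if w.min() <= 0:
        raise ValueError("precision matrix must be positive definite")
    if partial_correlation:
        d = np.sqrt(np.diag(theta))
        r = -theta / np.outer(d, d)
    else:
        cov = np.linalg.inv(theta)
        d = np.sqrt(np.diag(cov))
        r = cov / np.outer(d, d)
    r = np.clip(r, -_CLIP, _CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return 0.5 * (z + z.T)


def compute_dynamic_connectome(
    ts,
    taper: TaperSpec,
    cfg: WindowEstimatorConfig = None,
) -> DynamicConnectome:
    """Windowed glasso connectivity for one subject.

    The penalty is ``cfg.lambda_selected`` if set, otherwise chosen by
    :func:`select_lambda` on the subject's full series.  Window covariances
    are standardized to the correlation scale before the lasso (see
    ``_standardize``); the same convention is used during penalty
    selection.
    """
    if cfg is None:
        cfg = WindowEstimatorConfig()
    data = ts.data
    P, T = data.shape
    L = taper.window_length
    W = count_windows(T, L, cfg.step)
    lam = cfg.lambda_selected
    if lam is None:
        lam = select_lambda(data, cfg.lambda_grid, cfg.cv_folds,
                            tol=cfg.glasso_tol, max_iter=cfg.glasso_max_iter)
    starts = np.arange(W) * cfg.step
    stack = np.empty((W, P, P))
    for wi, s in enumerate(starts):
        seg = data[:, s:s + L]
        S = _standardize(weighted_covariance(seg, taper.weights))
        theta = glasso_precision(S, lam, tol=cfg.glasso_tol,
                                 max_iter=cfg.glasso_max_iter)
        stack[wi] = precision_to_z(theta, cfg.partial_correlation)
    return DynamicConnectome(
        subject_id=ts.subject_id,
        z_stack=stack,
        window_starts=starts,
        window_length=L,
        lambda_selected=float(lam),
    )
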