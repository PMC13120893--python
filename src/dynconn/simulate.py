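"""Synthetic cohort generation from covariate-coupled Markov-switching states.

Each subject's node time series is drawn from a small set of latent
covariance "states": a per-subject Markov chain selects the active state at
every time point, and the observation is a Gaussian vector with that
state's covariance plus isotropic noise.  A BMI-like covariate modulates,
on the log-odds scale, the self-transition probability of one target state,
so that heavier synthetic subjects dwell longer in that state.  This plants
a recoverable ground truth for every downstream stage: the state
covariances are the patterns clustering should find, and the dwell-time
coupling is the association the statistics stage should detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .io import SubjectTimeSeries, write_matrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_state_covariances",
    "default_transition_matrix",
    "simulate_cohort",
    "simulate_state_sequences",
    "write_fixture",
]

#: Plausible adult BMI range used to truncate the covariate distribution.
BMI_BOUNDS = (16.0, 46.0)


def default_transition_matrix(n_states: int, self_prob: float = 0.985) -> np.ndarray:
    """Row-stochastic matrix with common self-transition probability.

    The default self-transition of 0.985 gives a mean dwell of ~67 time
    points, comparable to the sliding-window length so that most windows
    are dominated by a single state.
    """
    if n_states < 1:
        raise ValueError("n_states must be positive")
    if n_states == 1:
        return np.ones((1, 1))
    off = (1.0 - self_prob) / (n_states - 1)
    mat = np.full((n_states, n_states), off)
    np.fill_diagonal(mat, self_prob)
    return mat


def _block_slices(n_nodes: int, n_blocks: int = 3) -> list[slice]:
    bounds = np.linspace(0, n_nodes, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _shrink_to_pd(corr: np.ndarray, min_eig: float = 0.05) -> np.ndarray:
    """Shrink a symmetric unit-diagonal matrix toward identity until its
    smallest eigenvalue is at least ``min_eig``."""
    w = np.linalg.eigvalsh(corr).min()
    if w >= min_eig:
        return corr
    gamma = (1.0 - min_eig) / (1.0 - w)
    out = gamma * corr + (1.0 - gamma) * np.eye(corr.shape[0])
    return out


def default_state_covariances(
    n_nodes: int, n_states: int = 4, target_state: int = 3
) -> list[np.ndarray]:
    """Block-structured state correlation matrices with a distinctive target.

    Nodes are split into three contiguous blocks (think of them as small
    functional networks).  Each state emphasizes a different block; the
    target state has an elevated "visual-network-like" block with positive
    coupling to one neighboring block and negative coupling to the other,
    so its pattern is clearly separable from the rest.  All matrices are
    unit-diagonal and strictly positive definite.
    """
    if n_nodes < 6:
        raise ValueError("need at least 6 nodes for block-structured states")
    if not (1 <= target_state <= n_states):
        raise ValueError("target_state must be in 1..n_states")
    blocks = _block_slices(n_nodes, 3)

    def blocky(spec: list[tuple[int, int, float]]) -> np.ndarray:
        m = np.eye(n_nodes)
        for bi, bj, v in spec:
            r, c = blocks[bi], blocks[bj]
            if bi == bj:
                sub = np.full((r.stop - r.start,) * 2, v)
                np.fill_diagonal(sub, 1.0)
                m[r, c] = sub
            else:
                m[r, c] = v
                m[c, r] = v
        return m

    templates: list[list[tuple[int, int, float]]] = [
        # strong first-block intra plus moderate secondary block
        [(0, 0, 0.70), (1, 1, 0.35)],
        # globally weak connectivity
        [(0, 0, 0.15), (1, 1, 0.15), (2, 2, 0.15)],
        # target-like: strong third block, signed cross-block coupling
        [(2, 2, 0.80), (0, 2, 0.35), (1, 2, -0.30)],
        # second-block dominated with positive cross coupling
        [(1, 1, 0.60), (0, 1, 0.30)],
    ]
    covs = []
    for k in range(n_states):
        spec = templates[k % len(templates)]
        if k >= len(templates):
            # extra states: attenuated copies so every state stays distinct
            atten = 0.6 ** (k // len(templates))
            spec = [(bi, bj, v * atten) for bi, bj, v in spec]
        covs.append(_shrink_to_pd(blocky(spec)))
    if n_states >= 3:
        # place the distinctive target-like pattern at the requested index
        i, j = target_state - 1, 2
        covs[i], covs[j] = covs[j], covs[i]
    return covs


@dataclass
class SimulationConfig:
    """Parameters of the Markov-switching cohort simulation.

    ``dwell_coupling`` is the per-unit-covariate increment, on the log-odds
    scale, applied to the target state's self-transition probability; the
    remaining mass of that row is renormalized proportionally, so the row
    stays stochastic for any coupling strength.
    """

    n_subjects: int = 60
    n_nodes: int = 10
    n_timepoints: int = 800
    n_states: int = 4
    state_covariances: Optional[Sequence[np.ndarray]] = None
    base_transition: Optional[np.ndarray] = None
    covariate_mean: float = 26.5
    covariate_sd: float = 4.5
    dwell_coupling: float = 0.1
    target_state: int = 3
    age_range: tuple[float, float] = (22.0, 37.0)
    gender_proportion: float = 0.48
    noise_sd: float = 0.2
    ar_coeff: float = 0.0
    initial_state: Optional[int] = None
    tr_seconds: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_nodes", "n_timepoints", "n_states"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not (0.0 <= self.gender_proportion <= 1.0):
            raise ValueError("gender_proportion must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (1 <= self.target_state <= self.n_states):
            raise ValueError("target_state must be in 1..n_states")
        if self.n_states == 1:
            self.dwell_coupling = 0.0  # a single state cannot be modulated
        if self.state_covariances is None:
            if self.n_states == 1:
                self.state_covariances = [np.eye(self.n_nodes)]
            else:
                self.state_covariances = default_state_covariances(
                    self.n_nodes, self.n_states, self.target_state
                )
        self.state_covariances = [
            np.asarray(c, dtype=float) for c in self.state_covariances
        ]
        if len(self.state_covariances) != self.n_states:
            raise ValueError("need one covariance per state")
        for k, cov in enumerate(self.state_covariances, start=1):
            if cov.shape != (self.n_nodes, self.n_nodes):
                raise ValueError(f"state {k} covariance has wrong shape")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"state {k} covariance is not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(
                    f"state {k} covariance is not positive definite"
                )
        if self.base_transition is None:
            self.base_transition = default_transition_matrix(self.n_states)
        self.base_transition = np.asarray(self.base_transition, dtype=float)
        if self.base_transition.shape != (self.n_states, self.n_states):
            raise ValueError("base_transition has wrong shape")
        rowsums = self.base_transition.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-12):
            raise ValueError("base_transition rows must sum to 1")
        if (self.base_transition < 0).any():
            raise ValueError("base_transition entries must be nonnegative")


@dataclass
class GroundTruth:
    """Latent truth of a simulated cohort."""

    cohort: pd.DataFrame
    state_sequences: np.ndarray  # (n_subjects, T), labels 1..K
    self_transition: np.ndarray  # realized target-state self-transition prob
    target_state: int
    config: SimulationConfig


def planted_z_patterns(cfg: SimulationConfig) -> np.ndarray:
    """Fisher-z upper-triangle pattern of each state's correlation matrix.

    Reference targets for centroid-recovery checks: row k is the
    upper-triangle vector of atanh(corr(state k)) including the isotropic
    observation noise on the diagonal.
    """
    iu = np.triu_indices(cfg.n_nodes, k=1)
    out = np.empty((cfg.n_states, iu[0].size))
    for k, cov in enumerate(cfg.state_covariances):
        noisy = cov + cfg.noise_sd**2 * np.eye(cfg.n_nodes)
        d = np.sqrt(np.diag(noisy))
        r = noisy / np.outer(d, d)
        out[k] = np.arctanh(np.clip(r[iu], -0.999999, 0.999999))
    return out


def subject_transition_matrix(cfg: SimulationConfig, covariate: float) -> np.ndarray:
    """Per-subject transition matrix with covariate-modulated target dwell."""
    mat = cfg.base_transition.copy()
    t = cfg.target_state - 1
    p0 = mat[t, t]
    if cfg.dwell_coupling == 0.0:
        return mat
    if p0 <= 0.0 or p0 >= 1.0:
        raise ValueError(
            "dwell coupling requires target self-transition strictly in (0, 1)"
        )
    p_new = float(expit(logit(p0) + cfg.dwell_coupling * (covariate - cfg.covariate_mean)))
    scale = (1.0 - p_new) / (1.0 - p0)
    mat[t, :] *= scale
    mat[t, t] = p_new
    if (mat[t, :] < 0).any() or (mat[t, :] > 1).any():
        raise ValueError("renormalized transition row left [0, 1]")
    return mat


def _draw_cohort(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = BMI_BOUNDS
    a = (lo - cfg.covariate_mean) / cfg.covariate_sd
    b = (hi - cfg.covariate_mean) / cfg.covariate_sd
    bmi = truncnorm.rvs(
        a, b, loc=cfg.covariate_mean, scale=cfg.covariate_sd,
        size=cfg.n_subjects, random_state=rng,
    )
    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=cfg.n_subjects)
    female = rng.random(cfg.n_subjects) < cfg.gender_proportion
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i+1:04d}" for i in range(cfg.n_subjects)],
            "bmi": bmi,
            "age": np.round(age, 1),
            "gender": np.where(female, "female", "male"),
        }
    )


def _simulate_chain(
    trans: np.ndarray, n_steps: int, rng: np.random.Generator,
    initial_state: Optional[int],
) -> np.ndarray:
    k = trans.shape[0]
    states = np.empty(n_steps, dtype=np.int64)
    if initial_state is None:
        s = int(rng.integers(k))
    else:
        s = initial_state - 1
    cum = np.cumsum(trans, axis=1)
    u = rng.random(n_steps)
    for t in range(n_steps):
        states[t] = s
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, k - 1)  # guard against cumulative rounding at 1.0
    return states


def simulate_state_sequences(cfg: SimulationConfig) -> GroundTruth:
    """Simulate the cohort and its latent state sequences only.

    Fast path for studies that operate on state labels (dwell-time metrics,
    null calibration) and do not need the Gaussian observations.
    """
    rng = np.random.default_rng(cfg.seed)
    cohort = _draw_cohort(cfg, rng)
    seqs = np.empty((cfg.n_subjects, cfg.n_timepoints), dtype=np.int64)
    probs = np.empty(cfg.n_subjects)
    t = cfg.target_state - 1
    for i, bmi in enumerate(cohort["bmi"].to_numpy()):
        trans = subject_transition_matrix(cfg, bmi)
        probs[i] = trans[t, t]
        seqs[i] = _simulate_chain(trans, cfg.n_timepoints, rng, cfg.initial_state) + 1
    return GroundTruth(
        cohort=cohort,
        state_sequences=seqs,
        self_transition=probs,
        target_state=cfg.target_state,
        config=cfg,
    )


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[SubjectTimeSeries], GroundTruth]:
    """Simulate node time series for a whole cohort.

    At each time point the observation is ``L_s @ eta + noise`` where
    ``L_s`` is the Cholesky factor of the active state's covariance.  With
    a nonzero ``ar_coeff`` phi, innovations are blended into an AR(1)
    recursion ``x_t = phi x_{t-1} + sqrt(1-phi^2) e_t`` to mimic temporal
    autocorrelation.  Deterministic given ``cfg.seed``.
    """
    truth = simulate_state_sequences(cfg)
    rng = np.random.default_rng((cfg.seed, 1))  # independent observation stream
    chols = [np.linalg.cholesky(c) for c in cfg.state_covariances]
    phi = cfg.ar_coeff
    subjects = []
    for i, sid in enumerate(truth.cohort["subject_id"]):
        eta = rng.standard_normal((cfg.n_nodes, cfg.n_timepoints))
        seq = truth.state_sequences[i] - 1
        x = np.empty_like(eta)
        # apply each state's Cholesky over runs of constant state
        boundaries = np.flatnonzero(np.diff(seq)) + 1
        for a, b in zip(np.r_[0, boundaries], np.r_[boundaries, len(seq)]):
            x[:, a:b] = chols[seq[a]] @ eta[:, a:b]
        if phi != 0.0:
            innov = x * np.sqrt(1.0 - phi**2)
            x = np.empty_like(innov)
            x[:, 0] = innov[:, 0] / np.sqrt(1.0 - phi**2)
            for t in range(1, x.shape[1]):
                x[:, t] = phi * x[:, t - 1] + innov[:, t]
        if cfg.noise_sd > 0:
            x = x + cfg.noise_sd * rng.standard_normal(x.shape)
        subjects.append(
            SubjectTimeSeries(subject_id=sid, data=x, tr_seconds=cfg.tr_seconds)
        )
    return subjects, truth


def write_fixture(
    out_dir: str | Path,
    subjects: Sequence[SubjectTimeSeries],
    truth: GroundTruth,
) -> dict:
    """Write a simulated cohort to disk and return the manifest.

    Layout: one TSV per subject (rows = time points), ``cohort.csv``,
    ``ground_truth.json`` and ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts_files = []
    for sub in subjects:
        fname = f"{sub.subject_id}_timeseries.tsv"
        write_matrix(out_dir / fname, sub.data)
        ts_files.append(fname)
    truth.cohort.to_csv(out_dir / "cohort.csv", index=False)
    gt = {
        "target_state": truth.target_state,
        "self_transition": truth.self_transition.tolist(),
        "state_sequences": {
            sid: truth.state_sequences[i].tolist()
            for i, sid in enumerate(truth.cohort["subject_id"])
        },
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh)
    manifest = {
        "seed": truth.config.seed,
        "n_subjects": len(subjects),
        "tr_seconds": truth.config.tr_seconds,
        "timeseries": ts_files,
        "cohort": "cohort.csv",
        "ground_truth": "ground_truth.json",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
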