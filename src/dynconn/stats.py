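"""Covariate-adjusted association testing and group contrasts.

BMI is related to (a) per-state temporal metrics (FW, MDT) and (b)
per-node temporal variability of efficiency metrics, by partial Pearson
correlation controlling age and gender, with Benjamini-Hochberg FDR
correction within each test family.  Weight-group contrasts
(healthy vs overweight, healthy vs obese) use Welch two-sample t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import assign_bmi_group
from .states import StateTemporalMetrics
from .topology import TopologyVariability

__all__ = [
    "AssociationResult",
    "GroupContrast",
    "partial_pearson",
    "fdr_adjust",
    "associate_state_metrics",
    "associate_topology",
    "group_contrasts",
]

ALPHA = 0.05


@dataclass
class AssociationResult:
    """One covariate-adjusted correlation test."""

    family: str
    target: str
    r: float
    p_raw: float
    p_corr: float
    n: int


@dataclass
class GroupContrast:
    """One two-group Welch contrast (negative t: first group lower)."""

    family: str
    target: str
    group_a: str
    group_b: str
    t: float
    p_raw: float
    p_corr: float
    n_a: int
    n_b: int


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation of x and y after removing covariate effects.

    Both variables are residualized on [intercept, covariates] by least
    squares; the correlation of the residuals is tested with
    ``t = r * sqrt((n - 2 - q)/(1 - r^2))`` on ``n - 2 - q`` degrees of
    freedom (q = number of covariates), two-sided.  Incomplete cases are
    dropped pairwise.  Returns ``(r, p, n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(C).all(axis=1)
    x, y, C = x[mask], y[mask], C[mask]
    n, q = len(x), C.shape[1]
    if n <= q + 3:
        raise ValueError(f"too few complete cases (n={n}) for {q} covariates")
    design = np.column_stack([np.ones(n), C])
    beta, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ beta
    rx, ry = resid[:, 0], resid[:, 1]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant residuals; correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - q
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p), n


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _covariate_matrix(cohort: pd.DataFrame) -> np.ndarray:
    gender01 = (cohort["gender"] == "female").astype(float).to_numpy()
    return np.column_stack([cohort["age"].to_numpy(float), gender01])


def _finalize(family: str, rows: list[dict]) -> list[AssociationResult]:
    if not rows:
        return []
    p_corr = fdr_adjust([row["p_raw"] for row in rows])
    return [
        AssociationResult(family=family, target=row["target"], r=row["r"],
                          p_raw=row["p_raw"], p_corr=float(pc), n=row["n"])
        for row, pc in zip(rows, p_corr)
    ]


def associate_state_metrics(
    metrics: StateTemporalMetrics,
    cohort: pd.DataFrame,
    covariate: str = "bmi",
    joint_family: bool = True,
) -> list[AssociationResult]:
    """Partial correlations of FW and MDT per state (and NT) with BMI.

    FW and MDT across all states form one FDR family of 2k tests
    (``joint_family=False`` corrects FW and MDT separately, k tests each);
    NT is a single test reported uncorrected.  Subjects with undefined MDT
    for a state are dropped pairwise for that test only.
    """
    cohort = cohort.set_index(cohort["subject_id"].astype(str))
    subjects = [s for s in metrics.fw.index if s in cohort.index]
    if len(subjects) < len(metrics.fw.index):
        warnings.warn("some subjects missing from cohort table", stacklevel=2)
    coh = cohort.loc[subjects]
    C = _covariate_matrix(coh)
    xvals = coh[covariate].to_numpy(float)
    k = metrics.fw.shape[1]

    def rows_for(frame: pd.DataFrame, name: str) -> list[dict]:
        rows = []
        for st in frame.columns:
            y = frame.loc[subjects, st].to_numpy(float)
            try:
                r, p, n = partial_pearson(xvals, y, C)
            except ValueError as exc:
                warnings.warn(f"{name} state {st} untestable: {exc}",
                              stacklevel=3)
                continue
            rows.append({"target": f"{name}_state{st}", "r": r, "p_raw": p, "n": n})
        return rows

    results: list[AssociationResult] = []
    fw_rows = rows_for(metrics.fw, "fw")
    mdt_rows = rows_for(metrics.mdt, "mdt")
    if joint_family:
        results += _finalize("state_metrics", fw_rows + mdt_rows)
    else:
        results += _finalize("fw", fw_rows)
        results += _finalize("mdt", mdt_rows)
    try:
        r, p, n = partial_pearson(
            xvals, metrics.nt.loc[subjects].to_numpy(float), C
        )
    except ValueError as exc:
        warnings.warn(f"NT untestable: {exc}", stacklevel=2)
    else:
        results.append(AssociationResult(family="nt", target="nt", r=r,
                                         p_raw=p, p_corr=p, n=n))
    return results


def associate_topology(
    var: TopologyVariability,
    cohort: pd.DataFrame,
    covariate: str = "bmi",
) -> list[AssociationResult]:
    """Partial correlations of per-node CV with BMI, one family per metric.

    Degenerate (constant) CV columns are excluded and reported with a
    warning.
    """
    cohort = cohort.set_index(cohort["subject_id"].astype(str))
    results: list[AssociationResult] = []
    for metric, frame in var.cv.items():
        subjects = [s for s in frame.index if s in cohort.index]
        coh = cohort.loc[subjects]
        C = _covariate_matrix(coh)
        xvals = coh[covariate].to_numpy(float)
        rows = []
        for node in frame.columns:
            y = frame.loc[subjects, node].to_numpy(float)
            finite = y[np.isfinite(y)]
            if finite.size < 4 or np.ptp(finite) == 0:
                warnings.warn(
                    f"{metric} node {node}: degenerate CV column excluded",
                    stacklevel=2,
                )
                continue
            r, p, n = partial_pearson(xvals, y, C)
            rows.append({"target": f"{metric}_node{node}", "r": r,
                         "p_raw": p, "n": n})
        results += _finalize(metric, rows)
    return results


def group_contrasts(
    metrics: StateTemporalMetrics,
    cohort: pd.DataFrame,
    comparisons: tuple = (("healthy", "overweight"), ("healthy", "obese")),
    min_group_n: int = 2,
) -> list[GroupContrast]:
    """Welch t-tests of FW and MDT per state between BMI groups.

    The t statistic is ``mean(group_a) - mean(group_b)`` scaled, so a
    negative value means the first (healthy) group is lower.  All
    contrasts form one FDR family.
    """
    cohort = cohort.set_index(cohort["subject_id"].astype(str))
    groups = {
        sid: assign_bmi_group(cohort.loc[sid, "bmi"])
        for sid in metrics.fw.index if sid in cohort.index
    }
    rows: list[dict] = []
    for name, frame in (("fw", metrics.fw), ("mdt", metrics.mdt)):
        for st in frame.columns:
            for ga, gb in comparisons:
                ya = frame.loc[[s for s, g in groups.items() if g == ga], st]
                yb = frame.loc[[s for s, g in groups.items() if g == gb], st]
                ya = ya.to_numpy(float)
                yb = yb.to_numpy(float)
                ya, yb = ya[np.isfinite(ya)], yb[np.isfinite(yb)]
                if len(ya) < min_group_n or len(yb) < min_group_n:
                    raise ValueError(
                        f"group too small for {name} state {st}: "
                        f"{ga} n={len(ya)}, {gb} n={len(yb)}"
                    )
                res = sps.ttest_ind(ya, yb, equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
                if not np.isfinite(t) and np.isclose(ya.mean(), yb.mean()):
                    t, p = 0.0, 1.0  # zero-variance, equal-mean degenerate case
                rows.append({
                    "target": f"{name}_state{st}", "group_a": ga, "group_b": gb,
                    "t": t, "p_raw": p,
                    "n_a": len(ya), "n_b": len(yb),
                })
    p_corr = fdr_adjust([row["p_raw"] for row in rows])
    return [
        GroupContrast(family="group_contrasts", target=row["target"],
                      group_a=row["group_a"], group_b=row["group_b"],
                      t=row["t"], p_raw=row["p_raw"], p_corr=float(pc),
                      n_a=row["n_a"], n_b=row["n_b"])
        for row, pc in zip(rows, p_corr)
    ]


def results_frame(results) -> pd.DataFrame:
    """Tabulate association or contrast results as a DataFrame."""
    return pd.DataFrame([vars(r) for r in results])
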