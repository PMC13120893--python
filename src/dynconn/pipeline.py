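"""End-to-end orchestration of the dynamic functional network analysis.

Stages: cohort exclusions -> per-subject preprocessing -> sliding-window
glasso connectivity -> state clustering and temporal metrics -> dynamic
topology variability -> covariate-adjusted association statistics.  Each
stage logs its timing and parameters and can write plain-text artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dfc, preprocess, states, stats, topology
from .config import PipelineConfig
from .io import SubjectTimeSeries, read_cohort, read_timeseries, write_matrix

__all__ = ["PipelineResult", "load_cohort_dir", "run_pipeline"]

log = logging.getLogger("dynconn")


@dataclass
class PipelineResult:
    """Bundle of every stage's output."""

    cohort: pd.DataFrame
    exclusion_log: pd.DataFrame
    connectomes: list[dfc.DynamicConnectome]
    state_model: states.StateModel
    metrics: states.StateTemporalMetrics
    variability: Optional[topology.TopologyVariability]
    state_associations: list[stats.AssociationResult]
    topology_associations: list[stats.AssociationResult]
    contrasts: list[stats.GroupContrast]

    def significant(self, alpha: float = stats.ALPHA) -> pd.DataFrame:
        rows = [
            vars(r)
            for r in self.state_associations + self.topology_associations
            if r.p_corr < alpha
        ]
        return pd.DataFrame(rows)


def load_cohort_dir(
    input_dir: str | Path, tr_seconds: float | None = None
) -> tuple[pd.DataFrame, list[SubjectTimeSeries]]:
    """Load a cohort directory (cohort.csv + one TSV per subject).

    If a ``manifest.json`` is present it names the time-series files and
    the repetition time; otherwise every ``*_timeseries.tsv`` beside
    ``cohort.csv`` is taken, one per cohort row.
    """
    input_dir = Path(input_dir)
    cohort = read_cohort(input_dir / "cohort.csv")
    manifest_path = input_dir / "manifest.json"
    tr = tr_seconds
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        files = [input_dir / f for f in manifest["timeseries"]]
        tr = tr if tr is not None else manifest.get("tr_seconds")
    else:
        files = sorted(input_dir.glob("*_timeseries.tsv"))
    tr = tr if tr is not None else 0.72
    subjects = []
    for f in files:
        sid = f.name.replace("_timeseries.tsv", "")
        subjects.append(read_timeseries(f, subject_id=sid, tr_seconds=tr))
    ids = {s.subject_id for s in subjects}
    missing = set(cohort["subject_id"]) - ids
    if missing:
        log.warning("no time series for %d cohort subjects", len(missing))
    return cohort, subjects


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.1f s", stage,
                     time.perf_counter() - self.t0)

    return _Timer()


def run_pipeline(
    cohort: pd.DataFrame,
    subjects: Sequence[SubjectTimeSeries],
    cfg: PipelineConfig = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on an in-memory cohort.

    Subjects absent from the (post-exclusion) cohort table are skipped.
    When ``out_dir`` is given, stage artifacts are written there as
    TSV/CSV/JSON.
    """
    if cfg is None:
        cfg = PipelineConfig()
    from .io import apply_exclusions

    with _timed("exclusions"):
        cohort, excl_log = apply_exclusions(cohort, cfg.fd_threshold)
    keep = set(cohort["subject_id"])
    subjects = [s for s in subjects if s.subject_id in keep]
    if not subjects:
        raise ValueError("no subjects left after exclusions")

    if cfg.run_preprocess:
        with _timed("preprocess"):
            subjects = [
                preprocess.preprocess_subject(s, cfg.preprocess) for s in subjects
            ]

    with _timed("dfc"):
        taper = dfc.build_taper(cfg.window_length, cfg.gaussian_sigma)
        connectomes = [
            dfc.compute_dynamic_connectome(s, taper, cfg.estimator)
            for s in subjects
        ]

    with _timed("states"):
        model = states.fit_state_model(connectomes, cfg.cluster,
                                       k_fixed=cfg.k_fixed)
        metrics = states.cohort_temporal_metrics(model.state_vectors, model.k)
        log.info("selected k=%d", model.k)

    variability = None
    topo_assoc: list[stats.AssociationResult] = []
    if cfg.run_topology:
        with _timed("topology"):
            variability = topology.topology_variability(connectomes, cfg.topology)

    with _timed("associations"):
        state_assoc = stats.associate_state_metrics(
            metrics, cohort, joint_family=cfg.joint_family
        )
        if variability is not None:
            topo_assoc = stats.associate_topology(variability, cohort)
        contrasts: list[stats.GroupContrast] = []
        if cfg.run_group_contrasts:
            try:
                contrasts = stats.group_contrasts(metrics, cohort)
            except ValueError as exc:
                log.warning("group contrasts skipped: %s", exc)

    result = PipelineResult(
        cohort=cohort,
        exclusion_log=excl_log,
        connectomes=connectomes,
        state_model=model,
        metrics=metrics,
        variability=variability,
        state_associations=state_assoc,
        topology_associations=topo_assoc,
        contrasts=contrasts,
    )
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    """Write stage artifacts (centroids, state vectors, metrics, stats)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = result.state_model
    for st in range(1, model.k + 1):
        write_matrix(out / f"centroid_state{st}.tsv",
                     model.centroid_matrix(st), rows="node")
    with open(out / "state_vectors.tsv", "w") as fh:
        for sid, vec in model.state_vectors.items():
            fh.write(sid + "\t" + "\t".join(map(str, vec.tolist())) + "\n")
    pd.DataFrame(
        {"k": list(model.validity_curve), "cvi": list(model.validity_curve.values())}
    ).to_csv(out / "validity_curve.csv", index=False)
    fw = result.metrics.fw.stack().rename("fw")
    mdt = result.metrics.mdt.stack().rename("mdt")
    metrics_long = pd.concat([fw, mdt], axis=1).reset_index()
    metrics_long.columns = ["subject_id", "state", "fw", "mdt"]
    metrics_long.to_csv(out / "state_metrics.csv", index=False)
    result.metrics.nt.rename_axis("subject_id").to_csv(out / "transitions.csv")
    if result.variability is not None:
        rows = []
        for metric, frame in result.variability.cv.items():
            long = frame.stack().rename("cv").reset_index()
            long.columns = ["subject_id", "node", "cv"]
            long.insert(2, "metric", metric)
            rows.append(long)
        pd.concat(rows).to_csv(out / "topology_cv.csv", index=False)
    assoc = stats.results_frame(
        result.state_associations + result.topology_associations
    )
    assoc.to_csv(out / "associations.csv", index=False)
    if result.contrasts:
        stats.results_frame(result.contrasts).to_csv(
            out / "group_contrasts.csv", index=False
        )
    result.exclusion_log.to_csv(out / "exclusion_log.csv", index=False)
    summary = {
        "k": model.k,
        "n_subjects": int(len(result.cohort)),
        "significant": result.significant().to_dict(orient="records"),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
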