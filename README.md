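# dynconn

Dynamic functional network connectivity analysis: from multivariate
resting-state IC time courses to recurring whole-brain connectivity
states, their temporal dynamics, the temporal variability of graph
efficiency, and covariate-adjusted associations with body mass index.

## Who this is for

Researchers relating a subject-level covariate (here BMI) to *dynamic*
properties of brain functional networks. Static functional connectivity
averages over the scan; this package instead estimates connectivity in
tapered sliding windows, clusters the windowed matrices into recurring
"FC states", and asks whether the covariate predicts how long subjects
dwell in particular states and how variable their network topology is
over time.

## What it computes

For each subject with a node × time matrix **X** (P independent
components, T time points, repetition time TR):

- **Windowed connectivity.** A rectangle-convolved-Gaussian taper
  (L = 70 TR, σ = 3 TR) slides by 1 TR. Each window's weighted covariance
  S is fed to the graphical lasso
  `max_Θ log det Θ − tr(SΘ) − λ‖Θ‖₁,off` with λ chosen per subject by
  contiguous-block cross-validation; the precision is converted to
  correlations and Fisher z-transformed, giving a W × P × P stack.
- **FC states.** Windows at local maxima of connectivity variance are
  pooled across subjects and clustered by L1 (Manhattan) k-means
  (median updates, 100 restarts) for k = 2..10; an elbow (knee) criterion
  on the normalized within-cluster dispersion picks k; every window is
  then assigned to its nearest centroid. Per subject and state:
  fractional window FW (%), mean dwell time MDT (windows), and the
  number of transitions NT.
- **Topological variability.** Each window is binarized over a sparsity
  range (0.10–0.34), nodal efficiency and local efficiency are computed
  per node, aggregated across sparsity by AUC, and summarized over
  windows by the coefficient of variation CV = SD/mean.
- **Statistics.** Partial Pearson correlations (controlling age and
  gender) between BMI and each FW/MDT (one FDR family of 2k tests) and
  each node's CV (one FDR family per metric); Welch t contrasts between
  WHO BMI groups (healthy [18.5, 25), overweight [25, 30), obese ≥ 30).

A synthetic-cohort module generates Gaussian observations from K latent
covariance states switched by a per-subject Markov chain whose target-
state self-transition probability increases with a BMI-like covariate on
the log-odds scale — so every stage of the pipeline has a planted,
recoverable ground truth.

## Worked example

```python
import numpy as np
from dynconn import (SimulationConfig, simulate_cohort, build_taper,
                     WindowEstimatorConfig, compute_dynamic_connectome,
                     ClusterConfig, fit_state_model, cohort_temporal_metrics,
                     associate_state_metrics)

cfg = SimulationConfig(n_subjects=20, n_nodes=10, n_timepoints=400,
                       dwell_coupling=0.1, seed=2)
subjects, truth = simulate_cohort(cfg)

taper = build_taper(70, 3.0)
dcs = [compute_dynamic_connectome(s, taper, WindowEstimatorConfig(step=8))
       for s in subjects]
model = fit_state_model(dcs, ClusterConfig(k_range=(2, 6), n_replicates=10,
                                           seed=0))
metrics = cohort_temporal_metrics(model.state_vectors, model.k)
print("selected k:", model.k)
print(metrics.fw.head(3).round(1))
for r in associate_state_metrics(metrics, truth.cohort)[:3]:
    print(f"{r.target}: r={r.r:+.2f} pcorr={r.p_corr:.3f} (n={r.n})")
```

prints (windowed estimation takes ~20 s):

```
selected k: 4
             1     2     3    4
sub-0001   0.0  61.9  28.6  9.5
sub-0002  21.4  33.3  45.2  0.0
sub-0003  73.8  23.8   0.0  2.4
fw_state1: r=+0.28 pcorr=0.750 (n=20)
fw_state2: r=-0.15 pcorr=0.750 (n=20)
fw_state3: r=-0.09 pcorr=0.750 (n=20)
```

The elbow recovers the four planted covariance states, each subject's
window sequence yields per-state occupancy percentages (rows sum to
100%), and the association table reports the age/gender-adjusted partial
correlation of each temporal metric with the BMI-like covariate together
with its FDR-corrected p-value (nothing is significant at n = 20; the
planted dwell effect needs a larger cohort, see below).

## Command line

```bash
dynconn simulate --config sim.yaml --out cohort/      # synthetic fixture
dynconn run --input cohort/ --config cfg.yaml --out results/
dynconn dfc --input cohort/ --out dfc/                # or stage by stage
dynconn states --input dfc/ --out states/
dynconn topology --input dfc/ --out topo/
dynconn associate --metrics states/state_metrics.csv \
    --cohort cohort/cohort.csv --out associations.csv
```

All numeric parameters live in a YAML config; defaults follow the study
design (window 70 TR / 50.4 s, σ = 3 TR, step 1, k = 2..10 with 100
restarts, sparsity 0.10–0.34, FD threshold 0.25).

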