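# Methods

`dynconn` implements a state-based dynamic functional network connectivity
(dFNC) analysis for resting-state fMRI IC time courses, together with a
Markov-switching simulator that plants a recoverable ground truth for every
stage. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
establish.

## Pipeline model

Inputs are per-subject node-by-time matrices (independent-component time
courses, repetition time TR) and a cohort table with BMI, age, gender and
optional mean frame-wise displacement.

1. **Exclusions.** Rows with missing BMI/age/gender are removed, as are
   subjects with mean frame-wise displacement above 0.25; endocrine-history
   and recent-childbirth filters apply only when those optional columns
   exist and are otherwise logged as not evaluable. BMI groups use the WHO
   half-open intervals: underweight (0, 18.5), healthy [18.5, 25),
   overweight [25, 30), obese [30, ∞). The published bounds ("18.5–24.9",
   "25–29.9") leave (24.9, 25) undefined; the half-open convention makes
   group assignment a total function of BMI. Underweight subjects remain in
   correlation analyses but not in the three-group contrasts.

2. **Preprocessing** (per node): drop the first 10 time points; regress
   polynomial trends of order 0–3 in a single least-squares projection onto
   a Legendre basis (projection is order-independent and idempotent);
   despike; low-pass filter at 0.15 Hz. Despiking follows the classic
   1-D MAD scheme: residuals from a cubic robust baseline are scaled by
   1.4826·MAD, and scaled residuals |s| > c1 are compressed to
   `sign(s)·(c1 + (c2−c1)·tanh((|s|−c1)/(c2−c1)))` with c1 = 2.5,
   c2 = 4.0, so no output deviates from the baseline by more than c2 robust
   SDs. The low-pass is a zero-phase order-5 Butterworth applied
   forward-backward (no group delay; effective response is the squared
   magnitude). Threshold, cap, filter order and cutoff are configurable.

3. **Sliding-window connectivity.** The window is a rectangle of
   L = 70 TR (50.4 s at TR = 720 ms) convolved with a Gaussian of
   σ = 3 TR (kernel evaluated on ±⌈4σ⌉ integer offsets, cropped to the
   central L samples, renormalized to sum 1; the taper is renormalized over
   the cropped support rather than padded). The window slides by 1 TR by
   default, giving `⌊(T−L)/step⌋+1` windows (2,321 for 2,390 effective time
   points). Within each window a taper-weighted sample covariance,
   standardized to the correlation scale (the L1 penalty is not
   scale-invariant; standardization penalizes every edge equally and
   markedly improves solver conditioning), feeds an L1-penalized
   precision estimate (graphical lasso); the penalty λ is
   selected once per subject by 5-fold contiguous-block cross-validation on
   the full unwindowed series, scoring held-out Gaussian log-likelihood
   `log det Θ − tr(S_test Θ)` over a 10-point log-spaced grid from 0.03 to
   1.0. Contiguous folds respect temporal dependence; ties go to the
   smaller penalty. The precision is inverted to a covariance, normalized
   to correlations, clipped at |r| ≤ 1−1e-7 and Fisher z-transformed with a
   zero diagonal (a partial-correlation variant reads z from the negative
   scaled precision instead and is exposed as a flag). Degenerate
   zero-variance nodes within a window raise an error rather than
   propagating NaN.

   Numerics: the coordinate-descent glasso solver can cycle on strongly
   correlated tapered windows — the dual gap dips below tolerance and then
   diverges — at a rate of roughly one window in 10^4. A negative or
   sub-10×tol residual gap is treated as converged (a rounding artifact of
   an optimal solution); stubborn windows walk a fallback ladder —
   coordinate descent, LARS, then both at a 10× looser stopping tolerance
   (a gap ≤ 1e-3 is still tight for the downstream z-estimates; the two
   solvers agree to ~1e-4 where both converge) — and only failure of the
   whole ladder raises an error.

4. **State clustering.** Per subject, windows at strict interior local
   maxima of the upper-triangle connectivity variance are pooled as
   exemplars (plateaus contribute their first index; if no interior peak
   exists all windows are used, with a warning). Exemplars from all
   subjects are clustered by L1 (Manhattan) k-means — assignment to the
   nearest centroid with ties to the lowest index, component-wise-median
   updates, empty clusters re-seeded at the worst-fit point — taking the
   best of 100 random restarts by total L1 inertia, for each k in 2..10.
   The cluster number is chosen by an elbow criterion: the validity value
   for each k is the mean L1 distance of exemplars to their centroid,
   normalized by total dispersion (mean L1 distance to the global median),
   and the selected k is the point of maximum vertical gap below the chord
   joining the curve's endpoints (the standard knee rule). An earlier
   formulation using the curvature of a within/between-centroid-distance
   ratio proved unreliable: the mean between-centroid distance itself
   falls as clusters split, making that curve non-monotone in k, whereas
   the knee rule recovers the planted cluster number consistently across
   seeds and agrees with the curvature rule on clean convex curves. Flat
   curves fall back to the smallest k with a warning. The winning exemplar
   centroids then label every window of every subject in a single
   assignment pass (no further centroid updates, matching the
   initialize-and-assign convention of dFNC state analysis; iterative
   refinement is available behind a flag).

   From each subject's state sequence: fractional window FW (percent of
   windows per state), mean dwell time MDT (mean maximal-run length per
   state, in windows; undefined for unvisited states), and number of
   transitions NT. These satisfy exact identities — FW sums to 100%,
   FW·W/100 = (#runs)·MDT per state, NT = #runs − 1 — which the test suite
   asserts on every simulated subject. MDT is reported in windows;
   multiplying by TR·step converts to seconds.

5. **Dynamic topology.** Each windowed z-matrix is binarized over a
   sparsity grid (default 0.10–0.34 in steps of 0.01, a common connectome
   range keeping graphs sparse but mostly connected), retaining the
   ⌊s·E⌋ strongest edges by |z| with ties broken in upper-triangle index
   order (signed ranking available behind a flag). Per node and window,
   nodal efficiency (mean inverse shortest-path length to all other nodes;
   unreachable pairs contribute 0) and local efficiency (global efficiency
   of the neighbor-induced subgraph with the index node removed; nodes of
   degree < 2 score 0) are integrated across the sparsity grid by the
   trapezoid rule, and the temporal variability of the resulting AUC
   series is summarized as the coefficient of variation CV = SD/mean
   (sample SD, ddof = 1 by default; a nonpositive mean leaves CV undefined
   and flagged). Distances are computed by simultaneous breadth-first
   search via boolean matrix products, verified exactly against a
   Floyd-Warshall oracle on 10^4 random graphs.

6. **Statistics.** Associations with BMI are partial Pearson correlations
   controlling age and a 0/1 gender indicator: both variables are
   residualized on [1, age, gender] and the residual correlation is tested
   with `t = r·√((n−2−q)/(1−r²))`, two-sided. Incomplete cases (e.g.
   undefined MDT) are dropped pairwise per test. FW and MDT across all k
   states form one Benjamini-Hochberg FDR family of 2k tests by default
   (separate FW and MDT families are available as a flag since the
   published grouping is not fully explicit); each topology metric forms
   its own family across nodes; NT is a single uncorrected test. Group
   contrasts (healthy vs overweight, healthy vs obese, on FW and MDT per
   state) use Welch unequal-variance t-tests, signed so that negative t
   means the healthy group is lower, FDR-corrected as one family. States
   testable on too few complete cases are skipped with an explicit
   warning rather than aborting the family.

## Synthetic cohort generator

Each subject's series is drawn from K latent covariance states switched by
a per-subject Markov chain. Defaults emulate the study regime at desk
scale: P = 10 nodes in three contiguous blocks standing in for functional
networks, K = 4 states, T = 800 time points at TR = 0.72 s, BMI-like
covariate truncated-normal with mean 26.5, SD 4.5 on [16, 46], ages
uniform on 22–37, 48% female, isotropic observation noise SD 0.2. The
four default state correlation matrices are block-structured: one state
with a strong first block, one globally weak state, one "visual-network-
like" target state with a strong third block plus positive coupling to the
first block and negative coupling to the second, and one second-block
state; all are shrunk toward the identity just enough to keep the smallest
eigenvalue at 0.05. The base self-transition probability is 0.985 (mean
dwell ≈ 67 TR, commensurate with the 70-TR window so most windows are
dominated by one state). The covariate acts on the target state's
self-transition on the log-odds scale, `p = logistic(logit(p0) +
β·(BMI − mean))` with β = 0.1 per BMI unit by default, and the remaining
row mass is renormalized proportionally — rows stay stochastic for any β.
An optional AR(1) flag adds temporal autocorrelation; none is present by
default because the analysis pipeline does not model it.

What the generator does *not* emulate: hemodynamic filtering, scanner
drift and physiological noise spectra, spatially correlated artifacts,
inter-subject variability in state patterns, and the continuous (non-
discrete) character of real FC dynamics. Passing the planted-recovery
suite therefore demonstrates that the estimator chain is correct and
well-calibrated under the model's own assumptions, not that the published
effect sizes would reproduce on real HCP data.

## Validation design and problem sizes

The acceptance suite and `scripts/acceptance.py` run three planted
studies, sized to be informative at desk scale: cluster-number and
centroid recovery on n = 60 subjects (P = 10, T = 800, K = 4, window
step 4); dwell-coupling recovery on n = 150 subjects (T = 600, β = 0.1,
model order fixed at the planted k = 4, the elbow being validated by the
recovery study); and a null calibration of 200 cohorts (n = 60,
sequence-level simulation, β = 0) where the reported quantity is the
proportion of FW/MDT family tests declared significant at pcorr < 0.05.
Under the global null this per-test proportion is far below the nominal
0.05 because BH rejects rarely when nothing is true; the probability that
*some* test in a family rejects sits at the design level by construction
and is therefore not a useful pass/fail bound at 200 replicates.

## Known limitations

- Exemplar windows at variance peaks over-sample transition windows in a
  sharply switching simulation; with dwell times comparable to the window
  length some exemplars are state blends. Recovery still succeeds at the
  default separation, but much faster switching would degrade it.
- λ selection assumes a single stationary sparsity level per subject; a
  subject whose states differ strongly in conditioning receives a
  compromise penalty.
- The elbow criterion, like all of its operationalizations, is a heuristic;
  on curves without a clear knee it warns and falls back to the smallest
  candidate rather than guessing.
- Efficiency metrics are unweighted; weighted-graph variants and global
  network summaries are out of scope.
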