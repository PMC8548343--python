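# Methods

`chronnectome` implements a dynamic functional network connectivity
(dFNC) analysis chain for independent-component (IC) time courses:
tapered sliding-window connectivity with sparse inverse-covariance
regularisation, k-means decomposition of windowed connectivity into
recurring states with the L1 distance, per-subject state temporal
metrics, the quartile-discretised meta-state method, and the group
statistics used to compare dynamics metrics across cohorts.  A
hidden-state Markov simulator supplies cohorts with exact ground truth
so every stage can be validated without scan data.

## Input model and post-processing

The unit of input is a T×C matrix of component time courses (T
timepoints at repetition time TR seconds, C components).  The reference
configuration is T = 235 retained volumes (240 acquired, first 5
discarded), C = 30, TR = 2.5 s.  Before windowing, each column is
least-squares detrended (mean and slope removed) and low-pass filtered
with a 5th-order Butterworth at 0.15 Hz.  The filter is applied
forward–backward (`scipy.signal.sosfiltfilt`), i.e. zero phase: dwell
and transition metrics downstream are timing-sensitive, and a causal
filter would shift state boundaries by the group delay.  Detrending
precedes filtering so the filter does not ring on a linear drift.
Idempotence holds only for band-limited content: broadband input loses a
further ~1% RMS per pass because the passband gain of the squared
Butterworth response is not exactly unity near the cutoff.

## Sliding-window connectivity

Windows of `width_tr` = 22 TRs (55 s) slide in steps of 1 TR.  The
window count convention is `Nw = (T − width) // step`, giving 213
windows for T = 235 — the convention is fixed by that bookkeeping
identity.  Within a window, samples are weighted by a taper built as a
rectangle of length 22 convolved with a discrete Gaussian of σ = 3 TRs
(kernel support ±⌈4σ⌉), truncated to the window and normalised to sum 1.
The weighted covariance uses weighted-mean centring and the
frequency-weights unbiased divisor 1 − Σwᵢ², which reduces to the
ordinary n−1 sample covariance under uniform weights.

A 22-sample covariance of 30 components is singular, so each window's
covariance S is regularised by the graphical lasso (L1 penalty λ on
off-diagonal precision entries; `sklearn.covariance.graphical_lasso`).
λ is selected per subject by held-out window log-likelihood: for each of
`lambda_reps` random half-splits of the subject's windows, each
candidate λ is fitted on the mean covariance of the training half and
scored by `log det Θ − tr(S_test Θ)` on the held-out half; the best mean
score wins.  The `WindowConfig` default grid is `logspace(−3, 0, 10)`
with 50 repetitions; cohort-scale runs (pipeline default, acceptance
script) use the shorter grid (0.05, 0.1, 0.15, 0.25) with 5 repetitions
— 22-sample/30-component windows need λ ≳ 0.05 for a numerically stable
fit, and the held-out score surface is smooth enough that a 4-point grid
identifies the same neighbourhood.  Windowed fits use a relaxed
convergence tolerance (1e−3); the selected correlations change by ≪ the
Fisher-z noise floor while the fit is ~10× faster.

The reported connectivity value is the correlation matrix derived from
the regularised covariance Θ⁻¹ (config flag `fc_value` switches to the
partial correlation −Θᵢⱼ/√(ΘᵢᵢΘⱼⱼ)).  Correlations are clipped at
1 − 1e−7 and Fisher z-transformed (arctanh); the upper triangle is
vectorised in row-major (i<j) order into P = C(C−1)/2 = 435 pairs.

## State clustering

All subjects' windows are pooled (70 × 213 = 14,910 instances) and
clustered with k-means under the L1 (city-block) distance.  Centroid
updates are coordinate-wise medians — the L1-optimal prototype — which
makes total within-cluster L1 inertia provably non-increasing per Lloyd
iteration (asserted on every run).  Assignment ties go to the lower
state index; an emptied cluster is reseeded with the point farthest from
its centroid.  Clustering is two-stage: stage 1 clusters per-subject
exemplar windows (local maxima of across-pair FC variance; `all` is the
configurable alternative) with 10 random restarts and up to 500
iterations; stage 2 makes a single full-data pass initialised at the
stage-1 centroids.  Model-order diagnostics (mean silhouette, WCSS
elbow, Dunn index — all under L1) are reported per candidate k without
an automatic choice; k ∈ {2, 4} are the reference solutions.  The
quadratic-cost diagnostics are evaluated on a seeded subsample above
4,000 points.  Split-half reproducibility clusters two disjoint subject
halves plus 5 random half-size subsets and matches centroids by greedy
maximal Pearson correlation (Hungarian matching available behind the
same interface).

## Temporal metrics

From a subject's window label sequence: fractional windows (occupancy
per state), mean dwell time (mean maximal-run length per state, in
windows; seconds = windows × step × TR), and number of transitions
(label changes between consecutive windows).  A never-visited state's
dwell time is missing (NaN), not zero — zero would bias group means
downward.  The identities `transitions = runs − 1` and
`Σ dwell × run-count = Nw` are property-tested.

## Meta-state dynamics

Each window's z-vector is projected onto the k state centroids as
continuous loadings (Pearson correlation by default; regression weights
behind a flag).  Loadings are discretised to ±{1,2,3,4}: per pattern
dimension, the 25/50/75 percentiles (linear interpolation) of |loading|
over the reference windows define the magnitude quartile — a weight maps
to sign × (1 + number of percentiles strictly below its magnitude), so
boundary values fall in the lower bin and zero takes the + sign.  The
reference is the subject's own windows by default; a cohort-pooled
reference is configurable.  The four metrics are the number of distinct
meta-states, the number of meta-state changes, the span (maximum
pairwise L1 distance among occupied meta-states) and the total L1
distance along the trajectory.

A known limitation: per-subject quartile discretisation forces each
magnitude level to hold 25% of that subject's windows, so a subject who
never leaves one state still hops levels through estimation noise — at
22-TR-window noise levels the group ordering of n_changes/total_distance
is **not** a monotone readout of the hidden switching rate (mixed
windows additionally compress the loading range, which can reverse the
total-distance ordering).  The ordering is recovered when loadings track
the states with temporally smooth noise, the quartile reference is
cohort-pooled, and every subject visits both states; the test suite
probes exactly that regime.

## Group statistics

- One-way GLM: F for the group factor from a full-vs-reduced OLS
  comparison (statsmodels); optional nuisance covariates enter both
  models.
- Fisher's LSD post-hocs: pairwise t with the pooled omnibus error
  variance and residual df, no multiplicity adjustment, and *not* gated
  on the omnibus p.
- Cohen's d with (n−1)-weighted pooled SD.
- Hotelling's T² on occupancy profiles: two-sample with pooled
  covariance; one occupancy column is dropped automatically when rows
  sum to 1 (compositional redundancy).  With three groups both all-pairs
  T² and a MANOVA omnibus (Wilks' lambda; univariate fallback = one-way
  ANOVA) are reported, since either construction is defensible.
- TFNBS: edgewise pooled-variance t, enhanced over an ascending
  threshold ladder (step dh = max|t|/100 by default) by
  (component-size-in-edges)^E × h^H × dh with E = 0.5, H = 3; signed
  directions are enhanced separately and summed; family-wise error is
  controlled by the permutation distribution of the maximum enhanced
  score (5,000 permutations by default; desk-scale runs use 200–1,000).
  Subject-level input is each subject's mean Fisher-z vector over their
  windows in the given state — the group state-median map is
  descriptive, inference needs subject-level units.
- Spearman correlations (midrank ties, t-approximation p) between
  dynamics metrics and MAIA interoception dimensions, per group, with an
  optional 1.5·IQR outlier screen (flagged points are logged, never
  silently dropped).

## Synthetic cohort

Each subject is a first-order Markov chain over k = 2 hidden states
(sampled per TR); given the state, the observation is a zero-mean
multivariate Gaussian with that state's covariance (temporally white, so
the per-state covariance is exact ground truth; an AR(1) smoothing
coefficient, default 0, is available for realism studies).  State
covariances are block-structured with unit diagonal: 7 "network" blocks
over 30 components; the sparse state has weak within-block coupling
(0.25), the dense state strong within-block coupling (0.55) plus
positive/negative couplings (±0.3–0.35) among the first three blocks — a
triple-network-like configuration.  An indefinite request is repaired by
clipping eigenvalues below 1e−6 and re-normalising to unit diagonal.

The default cohort is 29 TM / 19 CM / 22 CW subjects.  Groups share the
two states but differ in chain parameters, chosen once as a plausible
planted effect structure: dense-state stationary occupancy 0.36 (TM),
0.30 (CW), 0.24 (CM) — a TM−CM occupancy effect of 0.12 — and total
switching rate 0.07/0.06/0.04 per TR, giving mean dwells of roughly 15–40
TRs so that most 22-TR windows are state-pure while each subject still
shows several transitions.  Window-level truth is the modal hidden state
within the window (ties to the lower label).  Per-subject seeds are
master_seed + subject ordinal.  What the generator does *not* emulate:
hemodynamic filtering and autocorrelation, spatial map estimation error,
scanner drift and motion residuals, and graded (non-Markov) state
mixtures — so passing recovery tests demonstrates correctness of the
analysis chain, not expected performance on real scans.

## Numerical and scale choices

- Determinism: a single master seed fans out additively (simulation,
  per-subject λ selection, clustering restarts, split-half resampling,
  permutations); reruns are byte-identical.
- Desk-scale problem sizes: the recovery checks and the acceptance
  script run the full 70 × 235 × 30 default cohort with the 4-point λ
  grid (~4 minutes); statistical calibration uses 2,000-replicate null
  simulations; TFNBS checks use 8-node graphs with 200 permutations and
  20 seeded replicates.
- Degenerate inputs: zero-variance components inside a window are
  floored at 1e−12 with a warning; constant |loading| columns map to
  level 1; singleton clusters are excluded from mean silhouette with a
  logged count.

## Worked configuration

The `AnalysisConfig` YAML tree serialises losslessly and rejects unknown
keys.  `k_values` defaults to (2, 4); α = 0.05; all module parameters
above are exposed under `window`, `clustering`, `metastate`, `stats`,
and `synthetic` blocks.
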