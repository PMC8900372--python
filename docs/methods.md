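# Methods

## Model and procedure

`pathsig` tests, for every ordered pair of time-matched trajectory edges
(sender, receiver) and every ligand-receptor pair (L, R) in a database,
whether L's expression dynamics along the sender edge and R's dynamics along
the receiver edge co-vary strongly enough to suggest signaling.

**Assumptions.** Expression is nonnegative and already normalized; the
supplied pseudotime is a meaningful ordering within each edge; RNA level is
a usable proxy for ligand/receptor activity (post-transcriptional
regulation is invisible to the method); populations can only interact when
their sampling-time labels coincide.  Scores are computed on the expression
scale supplied — no log transform is applied or assumed.

**Windows.** Each edge's [0, 1] pseudotime axis is split into `n_bins`
half-open bins (t = 1 joins the last bin).  Windows are indexed by their end
bin, running from L/2−1 to n_bins−1, so M = n_bins − L/2 + 1 windows
(92 at the defaults n_bins = 101, L = 20).  The first window spans L/2
bins and grows by one bin per step until it reaches L; adjacent windows
overlap in L−1 bins.  This is the minimal layout satisfying the stated
first-window length, ramp, and one-bin slide; a `full_length_only` flag
drops the ramp for sensitivity analysis.  Cells are weighted equally within
a window.  Empty windows take the value of the nearest non-empty window
(earlier window on ties; leading empties are back-filled).  Zero-filling
was rejected because it fabricates down-regulation where there is simply no
data.

**Score and null.** The score is the plain dot product xᵀy of the two
window profiles.  The null permutes the joint (edge, pseudotime) label
vector across all cells of the model — not just the two tested clusters —
destroying cluster specificity and temporal ordering at once; one shared
permutation per round is reused for every cluster pair and ligand-receptor
pair (rounds are exchangeable, so this is valid and much cheaper).  A
`permute_within_pair` option restricts shuffling to the two tested
clusters for sensitivity analysis.  p = max(c, 1)/N where c counts permuted
scores ≥ observed; ties count against the observed score.  BH-FDR is
applied within each cluster pair by default (the reporting unit); a
`global_fdr` flag pools all tests instead.  Edges with ≤ 2 cells are scored
but flagged `low_confidence`.

## Tunable parameters

| parameter | default | meaning / why |
|---|---|---|
| `window_size` L | 20 bins | window sizes 5–30 behave similarly; 20 balances smoothing against temporal resolution |
| `n_bins` | 101 | bins per edge; pseudotime resolution |
| `n_permutations` N | 100,000 | p-value floor 1/N = 0.00001 |
| `alpha` | 0.05 | BH-FDR level |
| `include_autocrine` | off | also test each edge against itself |
| `use_alignment` | off | DTW-align edges before scoring |
| `spline_df` | 8 | coefficients of the smoothing spline for alignment curves |
| `min_expressed_fraction` | 0 | optional expression prefilter; the permutation null already neutralizes never-expressed genes (observed and null scores both ≈ 0) |

## Alignment option

When pseudotime spans different amounts of real time on the two edges, the
per-cluster-pair alignment warps the receiver's time axis onto the
sender's.  The alignment curve pairs dimensions by database entry: dimension
k is pair k's ligand profile on the sender edge matched against pair k's
receptor profile on the receiver edge.  Profiles are z-scored first and
spline-smoothed after: standardizing puts genes of different magnitude on a
common scale, and smoothing afterwards shrinks flat (noise-only) genes
toward zero so that genes with genuine dynamics dominate the DTW cost.
DTW uses squared Euclidean local cost, the symmetric step set (→, ↓, ↘), no
band constraint, and a deterministic diagonal-first tie-break.  The aligned
score is the path-mean product rescaled to M terms, so a diagonal path
reproduces the plain dot product exactly and aligned/unaligned scores share
a scale; permuted data are aligned with the identical procedure, keeping
the null exchangeable.

Two structural facts, established analytically and confirmed by simulation:

* For co-monotone profiles the identity coupling is already near-optimal
  for the dot product (rearrangement argument), and a delayed ramp is still
  a ramp — there is no phase landmark to recover.  Alignment is therefore
  neutral-to-slightly-negative on monotone programs, and genuinely useful
  for transient (pulse-like) programs whose peak moves under a delay.
* The warp path is estimated from the database genes.  Its quality degrades
  when genes with real dynamics are a small minority of database entries:
  with 4 pulse pairs among 8 decoy pairs the planted aligned-score gain is
  recovered essentially always, while at 4 among 40 decoys roughly a third
  of replicates lose it.  Aligning on a curated dynamic gene set is advised
  for sparse databases.

## Synthetic data

The generator emulates a fitted trajectory's emission model: gene j on an
edge has mean μ(t) = g_a e^{−Kt} + g_b (1 − e^{−Kt}) and cells draw
N(μ(t), σ²) truncated at zero (the truncation bias is acceptable because
scoring makes no distributional assumption).  Defaults: two time-matched
edges, 200 genes, 150 cells/edge, uniform pseudotimes, σ = 0.5, background
genes constant in time at edge-independent levels U(0.5, 3) — for them the
model-wide permutation null is exact, which is what makes the calibration
test meaningful.

**Archetypes.** Planted pairs follow one of four shapes — both rising, both
falling, or the two opposing combinations.  All use the rate K* solving
(1 − e^{−K})/K = 1/2 (≈ 1.594), which makes rising and falling trends share
the time-averaged mean (g_a + g_b)/2: average-based methods cannot separate
the four archetypes, profile scoring can (the rearrangement inequality puts
co-trending dot products above opposing ones).

**Planted effect size.** Trend endpoints default to (0.5, 5.5).  This was
sized by a power calculation rather than taste: the detection margin of a
co-trending pair over the model-wide null is ≈ M·var_t(μ) = 92·0.051Δ²
(Δ = trend range), while the permutation score noise is
≈ 29·√(0.025Δ² + σ²) at the default geometry, giving a detection z of
about 2 at Δ = 3 (inadequate for the p-floor at N = 1000) and about 4.3 at
Δ = 5.

**Two planting regimes.** In the *equal-per-edge-mean* regime (the
four-archetype fixture) a planted gene is held constant at its trend's
time average on the edge it does not trend on.  This removes cluster
specificity entirely and isolates time coordination; absolute power against
the model-wide null is low by design there (the trending profile's
window-mean sits slightly below the pooled cell mean, offsetting the
covariance gain), but the archetype *ordering* of scores and p-values is
preserved.  In the *cluster-specific* regime (the mixed/FDR fixture)
planted genes sit at a low baseline (0.5) off their designated edge —
the realistic, detectable case: the method's intended signal is expression
that is both cluster-specific and time-coordinated.

**Lagged pairs** carry a transient Gaussian pulse (baseline → peak →
baseline, width 0.08 pseudotime, receptor delayed by lag/n_bins) instead of
a monotone trend, for the structural reason above.  The width is kept small
relative to typical lags so the delayed and undelayed programs actually
differ; at width ≈ lag the unaligned dot stays high (heavy pulse overlap)
and the path-length rescaling cancels the alignment gain — a closed-form
overlap calculation, not a tuning choice.

**What the simulator does not model:** dropout/zero inflation, UMI count
noise, library-size variation, correlated gene programs, more than two
edges per time label, or errors in the trajectory itself.  Passing tests
demonstrate correctness of the machinery and calibration under the emission
model — not robustness to misspecified pseudotime or sparse counts.

## Numerical choices

* Bin convention: bin = ⌊t·n_bins⌋ clipped to the last bin; deterministic
  and total on [0, 1].
* Imputation ties resolve to the earlier window; profile values never leave
  the range of observed cell values on the edge.
* Majority sampling-time ties resolve to the lexicographically smallest
  label; cluster pairs and output rows are sorted deterministically, so a
  fixed seed gives byte-identical outputs.
* Gene symbols are trimmed and matched case-insensitively; duplicate
  symbols collapse to the first occurrence with a warning.
* The spline basis uses df coefficients with uniformly spaced interior
  knots; constant and linear profiles are reproduced exactly.  Rows shorter
  than df points fall back to a reduced basis.
* All randomness flows from a single seed through NumPy `SeedSequence`
  spawning (simulation and permutation streams are independent).

## Problem sizes used in the checks

The acceptance script and test suite run the full pipeline at the default
scenario geometry (200 genes, 300 cells, 92 windows) with N = 1000
permutations for calibration/FDR (5 and 10 seeds respectively), N = 100,000
on a two-gene fixture for the p-value floor, 20 replicates for archetype
discrimination, and 100 random short curves for the DTW-versus-enumeration
check; the whole set completes in well under a minute per component on one
CPU.

## Known limitations

* Scores scale with expression magnitude, so cross-dataset score
  comparisons require comparable normalization.
* The permutation null is shared across tests within a round; p-values are
  individually exact but weakly dependent across pairs, which BH tolerates.
* Per-cluster-pair BH (the default) controls FDR within each reported pair,
  not globally; use `global_fdr` for a single pooled correction.
* Alignment (see above) needs a database in which dynamically expressed
  genes are not a vanishing minority, and cannot help monotone programs.
* Trajectory quality is taken as given: cells mis-assigned to edges or
  mis-ordered in pseudotime degrade profiles silently.
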