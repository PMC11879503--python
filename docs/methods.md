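# Methods

This note documents the models and procedures `netpsych` implements,
the defaults it ships, the numerical choices behind them, and what the
synthetic-data tests do and do not establish about real questionnaire
data.

## Synthetic questionnaire data

**Model.**  Dependence is specified on a latent Gaussian scale, either
as a precision matrix (so the *partial* correlations — the quantities
the network estimator targets — are controlled directly) or as a
correlation matrix.  Each latent column is pushed through its normal
CDF and the inverse CDF of a shifted beta-binomial on the instrument's
score range.  The beta-binomial's two parameters are set to match the
target mean exactly and the target SD whenever the target is
overdispersed relative to a plain binomial; a plain binomial (matching
the mean, with the closest achievable SD) is the fallback.  Sums of
yes/no or Likert items are binomial-shaped under homogeneous items;
real item heterogeneity overdisperses them, which is why the
beta-binomial, not the binomial, reproduces the study-scale SDs (a
binomial on a 0–8 subscale with mean 2.83 cannot have an SD above
1.35, while the observed SD is 2.08 — and that underdispersion also
concentrates total scores enough to unbalance median splits).

**Precision construction.**  Requested partials `ρ_ij` become
off-diagonals `−ρ_ij` on a unit diagonal.  If the matrix is not
positive definite, a diagonal ridge grows geometrically (50-step
budget) until it is; the achieved partials, which shrink under
inflation, are reported.  Requests that exhaust the budget fail
loudly, naming the largest-magnitude edges.

**What the generator does not emulate.**  Item-level response
processes (only subscale totals are modeled), measurement error beyond
the discretization, missingness (downstream analyses assume complete
cases), and any real-data deviation from a Gaussian copula (e.g.
tail dependence).  The latent-scale dependence also means observed
Spearman correlations are mild nonlinear transforms of the latent
Pearson values (`ρ_S = 6/π · arcsin(r/2)` before discretization), so
zero latent partials are not *exactly* zero observed partials.
Passing recovery tests therefore show the estimators work under a
well-specified bounded-discrete questionnaire model, not that any
particular empirical dataset satisfies that model.

**Study-scale fixture.**  `study_like_dataset` combines the eight
study marginals with a sparse default structure
(`DEFAULT_STUDY_EDGES`): within-instrument edges of 0.15–0.35 plus
weaker cross-instrument bridges, chosen once as a plausible sparse
topology.  It is deliberately sparser and weaker than a real clinical
sample — its mean nodewise predictability is ≈ 0.17 and global
strength ≈ 2.0, whereas densely interconnected empirical symptom
networks reach predictability averages near 0.5 and global strength
above 3 — so absolute levels of such data-dependent quantities are
fixture properties, not benchmarks.  Gender (47% girls) and age bands
(probabilities on 9–12 matching mean 10.39, SD 0.96) are drawn
independently of the scores unless a gender-specific edge perturbation
is requested.

**Seeding.**  One master seed; every stage draws from
`SeedSequence([master, stage_key])` with fixed per-stage keys, so
adding or reconfiguring a stage never perturbs another stage's draws.

## Network estimation

Spearman rank correlations (average ranks at ties) are used throughout
because subscale sums are bounded and skewed; rank correlations are
invariant to whether scores were z-scored first.  A non-positive-
definite rank-correlation matrix is repaired by clipping eigenvalues
at 1e-6 and rescaling to unit diagonal (deterministic, symmetric; a
flag records that repair happened).

The graphical lasso maximizes
`log det K − tr(RK) − λ Σ_{i≠j}|K_ij|` with an **unpenalized
diagonal**, by block coordinate descent on the working covariance
(compiled with numba; the bootstrap and permutation stages re-estimate
the network ~1e5 times, and the whole λ path is solved inside one
compiled call with warm starts).  Every public single-λ solve is
certified against the subgradient optimality conditions
(`Σ_ii = R_ii`; `Σ_ij − R_ij = λ sign(K_ij)` on active entries;
`|Σ_ij − R_ij| ≤ λ` elsewhere) at 1e-4; the test suite additionally
checks elementwise agreement with an independent proximal-gradient
optimizer.  Entries below 1e-8 in magnitude count as exact zeros.

Model selection: 100 log-spaced penalties from `λ_max = max|r_ij|`
(provably the empty network) down to `0.01 λ_max`; minimum EBIC with
γ = 0.5; ties resolved toward the larger penalty (sparser model).
Selected weights are reported as the penalized estimates without a
relaxed refit, matching common practice for these networks.  A known
consequence of that practice, quantified by the recovery simulations:
at p = 8, n = 1000 with five true partials of 0.15–0.3, all true edges
are essentially always recovered (≈ 98% of runs), but one to three
weak false-positive edges survive selection in a sizable minority of
runs (per-pair false-positive rate ≈ 0.025), so "all true edges and at
most one false positive" holds in roughly 75–85% of runs rather than
uniformly.

## Centrality, predictability, bridges

Conventions follow the field's standard software: strength
`Σ_j |w_ij|`; expected influence `Σ_j w_ij`; edge distances
`d_ij = 1/|w_ij|`; closeness is the reciprocal of the *sum* of
shortest-path distances (reachable nodes only, with the reachable
count reported, for disconnected graphs); betweenness uses the Brandes
convention (pairs counted once, endpoints excluded, tied shortest
paths split fractionally).  Bridge strength/EI sum cross-community
weights; bridge closeness is the reciprocal of the *mean* distance to
outside-community nodes; bridge betweenness counts shortest paths
between nodes of two different communities.  All of these are checked
exactly against exhaustive path-enumeration oracles at p ≤ 8.

Predictability is the nodewise-regression R² of each (z-scored) node
on all others — the variance-explained reading appropriate for
quasi-continuous subscale sums; for Gaussian data it converges to
`1 − 1/(K_ii Σ_ii)`.  Bridge nodes are those strictly above the 80th
percentile (linear interpolation) of a bridge index; ties at the
cutoff are excluded, which is the conservative reading of a strict
percentile rule.

## Bootstrap stability

Edge accuracy: B resamples with replacement, full re-estimation,
percentile 2.5/97.5 CIs (percentile, not BCa, matching the cited
tooling's default).  Difference tests declare a pair different when
the percentile CI of the bootstrap difference excludes zero; they are
symmetric and reflexively non-significant by construction.
Case-dropping uses the grid 0.10–0.70 plus 0.75 by default, sampling
without replacement; correlations with the full-sample centralities
are Pearson on raw (unstandardized) values; undefined correlations
(constant replicate vectors) count as failures.  The CS coefficient
returns the largest grid proportion with ≥ 95% of replicates ≥ 0.7 —
evaluated independently at each grid point (non-contiguous
qualification takes the largest, per the definition).  Defaults are
B = 1000; tests and examples run B ≈ 100–200 for speed, which is ample
for the properties they assert.  Degenerate resamples (a constant
column) are redrawn, at most ten times, with a log record.

## Permutation network comparison

Both groups are re-estimated under random reassignment of the pooled
rows to groups of the original sizes.  Statistics: M = max |edge
difference| (structure), S = |global strength difference|; p-values
use the add-one convention `(1 + #{perm ≥ obs}) / (1 + B)` so they are
never zero; edge-level p-values are BH-adjusted across the p(p−1)/2
pairs; centrality differences (strength, EI — plain sums, so the
permutation loop avoids path computations entirely) are tested the
same way.  The default is 10 000 permutations; calibration tests use
200.  One resolution constraint worth knowing: with B permutations the
smallest achievable BH-adjusted p is `m/(B+1)` for m edge tests, so
FDR-level detection among 28 edges needs B ≥ ~600 — power checks use
B = 1000.

The median split assigns strictly-below-median rows to the low group
and strictly-above to the high group, excluding ties at the median
(observed group sizes then do not sum to n, as in real analyses of
integer totals).  Two selection effects discovered in the null
pipeline tests are worth flagging for users: splitting on a *sum* of
nodes induces genuine dependence among those nodes within each half,
and genuinely alters subgroup covariance — so median-split subgroups
of even fully independent data are *not* a null case for subgroup
networks, DAGs, or the split-group comparison.  Gender/age contrasts
with labels independent of scores are exchangeable-null and calibrate
correctly.

## Bayesian networks

Scores are z-scored per column (the Gaussian BIC's optimum structure
is scale-invariant; this just fixes a convention), and all local
scores derive from the MLE covariance, so each (node, parent-set)
score costs O(|parents|³) after one O(np²) pass; scores are cached by
(node, parent set).  The local score is the maximized Gaussian
log-likelihood minus `(|parents| + 2)/2 · log n` (coefficients,
intercept, variance).  Hill climbing applies the best strictly
improving add/delete/reverse move (acyclicity enforced per move; a
near-singular parent covariance, eigenvalue < 1e-10, makes a move
inadmissible); the first climb starts empty, and each of the default
5 restarts perturbs the incumbent with 10 random legal moves before
re-climbing.  At p = 3 the search provably attains the exhaustive
optimum on every tested dataset.

CPDAG reduction keeps the skeleton, orients v-structures (colliders
with non-adjacent parents), and propagates with the standard closure
rules (no new v-structures, no directed cycles, and the two-parent
fork rule) — sufficient to complete the pattern of a DAG without
background knowledge.  Bootstrap tables count *CPDAG* presence
(orientation-agnostic skeletons) and direction conditional on
presence, with undirected edges contributing 0.5 to each direction, so
the two directions of a present pair always sum to 1.  The consensus
keeps pairs at presence ≥ 0.85, oriented when a direction exceeds 0.5;
exact 0.5/0.5 pairs are retained undirected and flagged; a reference
listing of every pair at presence ≥ 0.5 is always produced for
sensitivity reading.

## Pipeline

`run_study` executes descriptives (min/max/mean/SD, adjusted
Fisher–Pearson skewness, sample-adjusted excess kurtosis; Welch t and
pooled-SD Cohen's d between gender groups) → whole-sample network,
centralities, bridge selection → bootstrap stability → three
comparison contrasts (gender, age band, median split of the
instrument total) → consensus DAGs for the whole sample, age bands and
split halves.  Each stage writes its JSON before the next begins, uses
its own seed substream, and the report (sorted-key JSON, no
timestamps; provenance = config hash + seed + version) reproduces byte
for byte under a fixed config and seed.  An optional outlier
sensitivity mode re-runs the network stage excluding rows with any
|z| > 3.29 — a conventional normal-theory cutoff, configurable.

## Problem sizes in the shipped checks

The test and acceptance workloads were sized as the smallest runs that
make their assertions statistically meaningful: oracle equivalences at
p ≤ 8 (where exhaustive enumeration is exact), recovery and coverage
at n = 1000–10 000 with 10–50 replicates, permutation calibration with
200 null replicates of 200 permutations, and powered FDR detection
with 1000 permutations.  Defaults inside the package (B = 1000,
10 000 permutations) remain the analysis-scale settings.

## Known limitations

* Predictability uses nodewise linear regression; for severely
  discrete nodes a generalized nodewise model would differ.
* EBIC-selected lasso estimates are biased toward zero and admit
  occasional weak false positives (quantified above); no post-selection
  refit or thresholding is applied.
* The copula generator cannot express directionality; DAG recovery
  tests use the linear-Gaussian SEM sampler instead, whose scores are
  continuous rather than bounded integers.
* Hill climbing guarantees only local optimality beyond small p, and
  cross-sectional DAGs identify orientations only up to Markov
  equivalence (colliders); unmeasured confounding is out of model.
* Betweenness (and bridge betweenness) is computed and reported, but
  is known to be unstable under resampling; the CS coefficient makes
  that visible rather than hiding it.
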