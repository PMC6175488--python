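# Methods

## The model

Tip traits are modelled as correlated Brownian motion on a rooted,
ultrametric, strictly bifurcating time tree:

    vec(X) ~ N(1 ⊗ α, Σ ⊗ C)

where `X` is the n × p matrix of trait values (in practice PC or pPC scores
of aligned shapes), `α` the ancestral (phylogenetic) mean, `Σ` the p × p
per-unit-time trait covariance, and `C` the n × n matrix of shared
root-to-MRCA path lengths. Rate heterogeneity enters through strictly
positive scalars attached to edges: a *branch* scalar multiplies the rate of
one edge; a *clade* scalar multiplies the target edge and every descendant
edge. The effective rate of an edge is the product of all scalars covering
it, defaulting to 1 — all reported rates are therefore *relative to a
background of 1*, with the global rate scale absorbed into `Σ` (multiplying
every effective rate by c and dividing `Σ` by c leaves the likelihood
unchanged).

### Likelihood

The profile log-likelihood is computed in one post-order pruning pass
(independent contrasts): merging two child partials with variances v₁, v₂
yields a contrast with covariance (v₁+v₂)Σ and a parent partial with extra
variance v₁v₂/(v₁+v₂). The pass accumulates log|C|, the contrast
cross-product matrix S, and the GLS mean α̂ (the root partial). Profiling
gives `Σ̂ = S/n` and

    loglik = -½ (np log 2π + p log|C| + n log|S/n| + np).

No dense np × np matrix is formed; the pass is jit-compiled (numba) with a
pure-Python fallback, and is verified against an explicit kron(Σ, C) MVN
density on random small instances to 1e-8. `S` is singular when p > n−1 or
the data are degenerate; the likelihood is then −∞.

### Reversible-jump sampler

The state is a set of (edge, scope, scalar) entries. Priors: the shift count
is Poisson with mean 2 (configurable); given the count, occupied
(edge, scope) slots are uniform over all valid slots (branch on any edge,
clade on internal edges); scalars are log-uniform on [e⁻⁷, e⁷]. Moves and
acceptance ratios (L = likelihood ratio, K = current shift count, μ = prior
mean, w = move weights):

* **add** — uniform free slot, scalar drawn from its prior:
  A = L · μ/(K+1) · w_del/w_add;
* **delete** — uniform entry: A = L · K/μ · w_add/w_del;
* **resize** — Gaussian random walk on log scalar (sd 0.7), rejected outside
  the prior support: A = L;
* **move** — uniform adjacent edge (parent/sibling/child), same scope,
  rejected when invalid or occupied: A = L · deg(old)/deg(new).

`Σ` and `α` are profiled at every likelihood evaluation rather than sampled;
this keeps the trans-dimensional state small at the cost of targeting a
profile posterior rather than the full joint (a deliberate trade, consistent
with ML-style multivariate fitting). Defaults are desk-scale: 200 000
iterations, thinned every 100, first 50% discarded as burn-in. The sampler
is a pure function of (data, settings, seed); a run with likelihood
evaluation disabled reproduces the Poisson prior on the shift count (checked
to 10%). A guard aborts with a diagnostic if nothing has been accepted after
10% of the iterations.

Branch summaries are elementwise posterior medians of effective rates
(midpoint for even sample counts); *tip rates* are the medians on terminal
edges, used as species-specific rates downstream.

Because the global scale is absorbed in `Σ̂`, the posterior occasionally
represents a planted clade shift in its mirrored mode — background edges
scaled down instead of the clade scaled up. Inside/outside rate *ratios* are
invariant to this and are what recovery checks assert.

### ML clade rates

For named monophyletic clades (labels with fewer than 5 members are dropped
and logged), one multiplicative rate per clade applies to all crown-group
edges (optionally including the stem). Log-rates are optimized by
Nelder–Mead from the single-rate start point, so the fitted likelihood never
falls below the one-rate model; they are bounded to the sampler's prior
support [−7, 7] in log space. When the clades cover nearly every edge the
background is only a handful of deep spine edges and the profile likelihood
can climb monotonically to a finite asymptote at infinite common rate — the
relative-rate scale is then only weakly identified. The synthetic study
design therefore assigns clades to a *subset* of the tree
(`simulate.select_clades`, disjoint clades of 10–30 tips, remaining species
unlabeled), which anchors the background; recovery and null calibration are
well behaved there (null fits stay within [0.5, 2], a planted 10× clade is
recovered within [4, 25] at n = 100).

### Diagnostics

PSRF uses the standard between/within decomposition,
`sqrt(((n−1)/n·W + B/n)/W)`; values below 1.1 are taken as between-chain
convergence. ESS is `n / τ` with τ from Geyer's initial positive sequence
(autocovariance via FFT, paired sums truncated at the first non-positive
pair) and floored at 1 so ESS never exceeds n; 200 is the within-chain
convergence gate. Both gates *warn* in the pipeline rather than abort.

## Morphometrics

* **Procrustes distance** — both configurations centered and scaled to unit
  centroid size, then optimal rotation (SVD of the cross-covariance with the
  determinant forced positive: beaks are chiral, reflections are never
  allowed) and optimal rescaling; the full Procrustes distance
  `sqrt(1 − cos²γ)`. Rejection threshold for user discrepancy: 0.2.
* **GPA** — iterative center/scale/rotate-to-consensus with the consensus
  re-normalized to unit size each round, to a consensus change below 1e-8
  (max 200 iterations). Output shapes are centered, unit-size, and the
  alignment is invariant to input order and to similarity pre-transforms.
* **QC** is staged so that a corrupted markup never contaminates its own
  reference:
  1. *edge inversion* — an intrinsic chirality statistic (signed triple
     product of the axis between the two most-separated non-tomial landmarks
     and the left/right curve centroids); users whose sign opposes the
     majority are flagged. Rotation/translation/scale invariant and
     noise-robust, no consensus needed.
  2. *user discrepancy* — iterative peeling on the pairwise Procrustes
     distance matrix: repeatedly drop the single worst user whose mean
     distance to the remaining users is ≥ 0.2. Peeling prevents one outlier
     from dragging agreeing users over the threshold. With a single user the
     test is skipped and noted.
  3. *curve disorder and asymmetry* — against the consensus of users with no
     flags so far: arc-length positions of each user's semi-landmarks
     projected on the consensus polyline must be monotone (tolerance: half
     the mean inter-point spacing); left/right mean deviations differing by
     more than 50% of the larger flag asymmetric placement, with an absolute
     floor of 0.05 so pure noise is never flagged (the asymmetry criterion
     and floor are configurable since no printed value exists for them).
  The specimen's *measurement error* is the mean between-user Procrustes
  distance over accepted users (all users when fewer than two are accepted).
* **Averaging** — accepted users are GPA-aligned and averaged pointwise.
* **Sliding** — semi-landmarks move along local curve tangents (neighbour
  differences, curve endpoints taken from the bounding fixed landmarks) by
  the closed-form minimizer of thin-plate-spline bending energy against the
  consensus. The 3D polyharmonic kernel U(r) = −r is used (the sign that
  makes the energy form positive semi-definite). The displacement vector is
  scaled back so no point moves more than half its local spacing — curve
  order is preserved by construction, and since the objective is a convex
  quadratic the capped step still decreases it. Three passes by default,
  GPA re-run after each; the per-pass energy decrease is asserted in tests.
  Curves with fewer than 3 points and no endpoints are skipped with a
  warning.
* **PCA/pPCA** — PCA eigen-decomposes the covariance of vectorized aligned
  coordinates about the consensus. pPCA uses the GLS phylogenetic mean
  `â = (1'C⁻¹1)⁻¹1'C⁻¹X` and the evolutionary covariance
  `(X−1â)'C⁻¹(X−1â)/(n−1)` under a pure-Brownian C (no λ estimation inside
  pPCA); scores are GLS-centered data projected on its eigenvectors. On a
  star tree (C ∝ I) pPCA reduces exactly to PCA up to per-axis sign.
  Eigenvector signs follow the convention that the largest-magnitude entry
  is positive. Axis selection keeps the smallest leading set reaching 99%
  cumulative variance.

## Correlates

* Species age = terminal branch length. Competition index = per occupied
  grid cell, the count of *other* species sharing family, diet class, and
  foraging class, averaged over all the focal's occupied cells (cells with
  zero competitors included). Range size = summed cell areas; island
  proportion = island-cell area share; temperature/UVB = unweighted cell
  means. Clade distinctiveness = Euclidean distance between the clade
  centroid and the grand centroid of the selected score columns.
* The species table logs body mass, generation length, range size, and age;
  competitor counts are logged as log(1+x) since zero is common and
  well-defined positivity cannot be assumed. Tip rates enter the response as
  log rates by default (configurable flag).
* **PGLS** — residual covariance `λ·C_offdiag + diag(C)` (the off-diagonal
  Pagel parameterization). λ is estimated by a 0..1 profile-ML grid at step
  0.01 plus a bounded golden-section polish around the best cell —
  robustness over speed, since the profile can be flat. Coefficient SEs use
  the GLS residual variance with n−k degrees of freedom; p-values are
  two-sided t-tests with no multiple-testing correction. Adjusted R² is
  computed against the intercept-only GLS fit at the same λ. λ = 0 reduces
  exactly to OLS. Categorical predictors expand to treatment contrasts;
  interactions are product terms; rank deficiency raises an error naming the
  aliased terms.
* **VIF** — `1/(1−R²_j)` from regressing each predictor (with intercept) on
  the others; perfect collinearity reports +inf rather than raising.
* The clade-level table keeps clades with ≥ 5 members: clade rate,
  distinctiveness, richness, MRCA age, mean member range size, proportion of
  members with mostly-insular ranges (> 0.5 island share), and mean
  competition index. Clade-level PGLS runs on a clade tree built by pruning
  the species tree to one representative per clade.

## Synthetic data

The generator replaces museum specimens, consensus trees, and range rasters:

* **Trees** — constant-rate birth–death conditioned on the extant tip count
  via the general sampling approach (ultrametric, strictly positive branch
  lengths), delegated to dendropy. Trees are inputs to the method, not part
  of it.
* **Traits** — preorder Brownian simulation with per-edge effective rates;
  planted shifts use the same log-uniform scalar family as the inference
  prior, so recovery tests are well posed.
* **Markups** — a parametric beak template (4 fixed landmarks: tip, dorsal
  posterior, left/right tomial posteriors; three 25-point semi-landmark
  curves) plus iid Gaussian landmark noise per user (default sd 0.005 in
  template units ≈ distances of ~0.03, well below the 0.2 rejection
  threshold), with constructed corruptions: exact left/right block swaps,
  within-curve shuffles, and smooth low-frequency outlier deformations
  scaled to a target Procrustes distance. Species-level shape variation is
  generated by displacing the template along smooth orthonormal modes whose
  amplitudes evolve by (variable-rate) Brownian motion — so shape data carry
  true phylogenetic signal.
* **Predictors** — log-normal masses/generation lengths/range sizes, Beta
  island proportions, Gaussian climate, Poisson competitor counts; the
  response is design·β plus Gaussian error with covariance
  `σ²(λ·C_offdiag + diag C)` on the unit-diagonal-scaled tree covariance.
* **Grids** — abstract unit-square cells times a cell size (default 110 km;
  no map projection). Ranges grow by seeded flood fill to a target
  occupancy, giving spatial autocorrelation; island flags are Bernoulli;
  temperature/UVB are smooth latitudinal gradients plus noise. Nothing is
  claimed about the sensitivity of the competition index to cell size; it is
  a parameter.

What the generator does **not** emulate: mesh/scan artifacts, missing
landmarks, real climate fields, geographic projections, taxonomic error, or
tree uncertainty (a single fixed tree per run). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated model,
not robustness to those real-data complications.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale sizes chosen to keep the
whole suite in a few minutes on one CPU: 64–200-tip trees, p = 2 traits for
rate inference, 200 000-iteration chains, 50-specimen QC sweeps, 100 PGLS
replicates at n = 200. Every stochastic function takes an explicit seed;
pipeline stage seeds derive deterministically from one global seed, so a
single integer reproduces a full run bit for bit.

## Known limitations

* The RJ sampler targets a profile posterior (Σ, α maximized out), not the
  full joint; uncertainty in Σ is not propagated into rate posteriors.
* Relative-rate scales are weakly identified when scalars cover nearly all
  edges (see above); reported rates are meaningful relative to background 1.
* The pruning likelihood requires strictly bifurcating trees; polytomies are
  supported elsewhere (vcv-based pPCA and PGLS) but not in rate inference.
* pPCA assumes λ = 1 Brownian covariance; no within-pPCA signal estimation.
* The QC chirality test needs a defined left/right curve pair and at least
  two non-tomial landmarks; layouts without them skip rule (1).
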