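# Methods

## Data contract and standardization

Inputs are a genes × samples matrix of log expression ratios and a samples ×
condition-variables table. Condition variables are tagged binary when their
observed values are exactly {0, 1}, continuous otherwise; the tag is
overridable. Missing values are rejected rather than imputed — the intended
data class (two-color ratio arrays restricted to respiring cultures) is
complete, and silent imputation would distort the precision-matrix estimates
downstream.

Both transcripts and arrays are standardized to mean 0, variance 1 (sample
variance, n−1). The order of the double standardization is arrays first,
then transcripts, so the per-transcript slices that clustering consumes end
exactly standardized; the order (and a rows-only variant) is exposed as
configuration. Condition variables, binary ones included, are standardized
before regression: the reported Z-statistics are scale-invariant, so this
only fixes the scale on which effects are averaged.

One consequence of per-array standardization worth knowing: subtracting each
sample's mean across genes injects a small shared component (≈ −1/K
correlation) into every cluster eigengene. At the study's scale (K = 100,
n = 47) this is far below detection thresholds; in small-K simulations at
large n it is visible, which is why the simulation harnesses below
standardize transcripts only — the generator plants no array effects, so the
per-array pass has nothing to correct there.

## Clustering and eigengenes

K-means (Lloyd's algorithm, Euclidean distance, k-means++ seeding per
restart, convergence on stable assignments or 300 iterations) partitions the
standardized transcripts; the assignment minimizing within-cluster sum of
squares over `n_init` restarts is kept. Defaults: K = 100 clusters,
1000 restarts. K is not selected automatically; the package exposes it as
configuration.

Each cluster's samples × member-genes submatrix is decomposed by SVD and the
first left singular vector (length n_samples) is the eigengene. Only the
first eigengene is used. Its sign is arbitrary in the SVD, so it is fixed by
the majority rule: flip so the eigengene correlates positively with most of
its member genes, ties broken by positive correlation with the lowest-index
member. This makes downstream edge signs reproducible. `explained_fraction`
is D(1)²/ΣD(i)²; per-gene R² is the squared Pearson correlation with the
eigengene. Eigengenes are re-standardized across samples before regression.

## Spike regression

Model: y = Xβ + e, e ~ N(0, σ²I), with each coefficient under a point-mass
spike prior β_j ~ p_β·(improper flat slab) + (1−p_β)·δ₀, reparameterized by
the prior inclusion log-odds ℓ₀/2 = log p_β − log(1−p_β). The factorized
variational posterior q(β_j) = α_j N(μ_j, s_j²) + (1−α_j) δ₀ has the exact
coordinate update (c_j the residual inner product excluding j, d_j = x_jᵀx_j):

    μ_j = c_j/d_j,  s_j² = σ²/d_j,
    logit α_j = ℓ₀/2 + ½ log(2π s_j²) + μ_j²/(2 s_j²).

The ½ log(2π s_j²) term is forced by integrating the flat slab; dropping it
would both break the exactness of the update and decouple the penalty from
the sample size. The noise variance update that exactly maximizes the bound
given q is σ² = R′/(n − Σ_j α_j) with R′ = ‖y − X E[β]‖² +
Σ_j d_j α_j(1−α_j) μ_j²; the variational lower bound is therefore
non-decreasing over sweeps, which the implementation asserts at every sweep.

Restarts start from the empty model and sweep coordinates in a
restart-specific random order (all seeds derived deterministically from a
master seed). Converged restarts are deduplicated by support set (α > 0.5)
and Z-statistics are averaged over unique models with weights ∝ exp(lower
bound). Z-statistics are reported for *every* predictor — for excluded ones
they are the statistic of the predictor against the converged model's
residual, approximately standard normal under the null. Defaults: 500
restarts in the pipeline configuration; convergence at relative bound change
< 1e-8 or 1000 sweeps.

The penalty ℓ₀ = −F⁻¹(1 − 0.05/m) − log n + 2 log(1−p) − 2 log p (χ²₁
quantile F⁻¹, p = 0.95) is computed with m = the number of predictors in the
regression at hand (141 at the default dimensions). With the update above
this puts the inclusion threshold on an orthogonal design at |z| ≈ 4.95 for
m = 141, n = 47 — deliberately close to, and slightly stricter than, the
global Bonferroni calling threshold Z_crit = Φ⁻¹(1 − 0.025/14200) ≈ 4.65, so
penalty selection and edge calling are mutually consistent.

## Network assembly

One regression per eigengene response; condition variables are predictors
only, never responses, and condition–condition edges cannot occur.
Eigengene-pair evidence is aggregated across the two regression directions
by geometric p-value averaging (p-values floored at 1e-300 before taking
logs); condition→eigengene evidence is the single directed test. Edges
require p ≤ α/n_tests with n_tests = (K + C)·K — 14,200 at the default
dimensions, reproducing the operating threshold 0.05/14200 = 3.52×10⁻⁶ even
though only K(K−1) + KC = 14,100 directed tests exist; the convention is
kept for comparability and is slightly conservative. Edge sign comes from
the more significant direction's Z; pairs whose two directions disagree in
sign are kept (significance is the only calling criterion) but flagged
`discordant`. Network statistics report connected-node count, isolated
variables, and mean degree over connected nodes, overall and restricted to
condition nodes.

## WGCNA baseline

Soft-threshold adjacency |cor(Z)|^η over the combined gene + condition
columns Z = [Y, X], η = 1..10, selecting the η that maximizes the
scale-free-topology fit; clustering by PAM (deterministic BUILD + best-swap)
on 1 − adjacency. The scale-free index is the R² of log₁₀(frequency) against
log₁₀(mean connectivity) over 10 equal-width connectivity bins (occupied
bins only, ties between powers broken toward the smaller η). Equal-width
bins follow standard soft-threshold practice; logarithmic bins were tried
and rejected because single-hub tail bins flatten the fit and misrank
genuinely scale-free networks. PAM is implemented in-package (greedy BUILD
seeding, best-improvement SWAP) since no installed library provides
medoid-based clustering on a precomputed distance matrix.

## Synthetic data

The generator samples from the model itself: a sparse symmetric Θ_zz with
Bernoulli(edge_density) support, magnitudes interaction_strength·U(0.8, 1.2)
with random signs, and diagonal 1 + row absolute sum — diagonal dominance
rather than a random Cholesky factor, so the planted support is exact and
the minimum eigenvalue is ≥ 1 by Gershgorin. Θ_zx gets
Bernoulli(condition_density) support scaled by effect_size. Conditions are
half binary Bernoulli(0.5) indicators and half standard normal by default,
mirroring the presence/absence-flags-plus-rates mix of real condition
tables. Eigengenes are drawn row-wise from N(Γx, Θ_zz⁻¹); member genes are
their cluster's eigengene plus Gaussian noise with sd set so the expected
within-cluster R² equals target_r2 (default 0.73). Defaults emulate the
study shape: 47 samples, 1,419 genes, 100 clusters with a skewed size
distribution (median ≈ 12, range ≈ 4–44), 42 conditions.

`planted_link=(condition, cluster)` forces one guaranteed binary-condition
effect — the stress-indicator→stress-cluster motif used throughout the
recovery tests. What the generator does *not* emulate: array-level intensity
noise, dye bias, probe effects, non-Gaussian expression tails, or
correlated condition variables. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to those real-data artifacts.

## Simulation harnesses and problem sizes

The test suite and reproducibility script run the *full* pipeline
(clustering → eigengenes → network) on generated data and score called
edges against the planted supports, re-identifying planted clusters among
the K-means estimates by maximum-overlap assignment. Conditions used:

- Null calibration: 200 datasets, K = 20, C = 5, n = 47, equal clusters of
  12; the fraction of replicates with any called edge bounds the family-wise
  error rate.
- Structure recovery: 50 datasets, K = 20, C = 5, n = 500, edge_density
  0.05, interaction_strength 0.8, effect_size 1.0, target R² 0.73, equal
  clusters of 12, one planted binary-condition link.
- Best-subset equivalence: 100 orthogonalized designs, n = 60, q = 8, two
  true effects (0.35 and 0.75 in standardized units — one comfortably below
  and one near the inclusion threshold), vbsr support versus exhaustive
  enumeration of all 2⁸ supports under the closed-form variational score
  with profiled σ².

K-means restart counts inside these replicate loops are 10–50 (the single
full-scale pipeline default remains 1000), and vbsr restarts 5–20 (default
500): on these well-separated simulated instances additional restarts do not
change the selected optima, and the reduced counts keep the harnesses at
seconds per replicate.

## Numerical choices and degenerate inputs

- Zero-variance rows/columns are hard errors naming the offending slice, as
  are duplicated identifiers, missing values, and sample-set mismatches.
- σ² is floored at 1e-12 and its denominator n − Σα at 1e-3; p-values at
  1e-300 before log-averaging.
- SVD sign ties (exactly balanced positive/negative member correlations)
  resolve toward the lowest-index member.
- Scale-free fits with fewer than 3 occupied bins, or degenerate degree
  spread, score 0.
- The heatmap splits row blocks at merge heights above gap_fraction × the
  maximum merge height (complete linkage, Euclidean distance — the defaults
  of the plotting stack the original figure came from, exposed as options);
  gap_fraction = 1 yields a single block by construction.

## Known limitations

- Neighborhood selection reports conditional-dependence edges, not causal
  directions; bidirectional aggregation is symmetric by design.
- The ℓ₀ penalty assumes standardized predictors; unstandardized inputs
  shift the inclusion threshold.
- Eigengene estimation error is ignored by the regression stage. It is
  negligible at the default shape, but with few clusters, strong
  inter-cluster coupling, or very large n it can leak cascade correlation
  past the conditioning (see the standardization note above).
- PAM's best-improvement swap is O(n²K) per pass; at gene-plus-condition
  scale (≈1,461 variables, K = 100) a baseline run takes minutes, which is
  acceptable for a comparison method but not tuned for larger inputs.
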