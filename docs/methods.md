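# Methods

This note documents the statistical models, the defaults and the design
choices behind the package, in the order the pipeline runs them. No
empirical claim is made here beyond what the test suite and
`scripts/acceptance.py` compute.

## Sample representation and proportion estimation

A cohort is a cell × feature matrix with per-cell sample ids and cluster
labels (`CellDataset`). Cluster and sample names are sorted
lexicographically once at load; every downstream matrix is indexed by that
fixed order, which makes all outputs deterministic and permutation-safe.

Sample `l` is summarized by its cluster distribution. Raw frequencies
`z_lk / N_l` are noisy for low-coverage samples and zero for unobserved
clusters, so we use the mode of a Dirichlet–multinomial posterior:

    z_l ~ Multinomial(N_l, θ),  θ ~ Dirichlet(α),  α_k = (N_k / N) · c.

The prior mass `c` (default **0.1**, i.e. one tenth of a pseudo cell per
sample) is deliberately weak: it guards against zeros without distorting
well-covered samples. `c → 0` gives empirical proportions exactly; `c → ∞`
shrinks every sample to the global cluster distribution. Both limits are
asserted in tests. A zero-cell sample is an error; `c = 0` with a missing
cluster yields a zero proportion and a warning.

## Transport cost and Wasserstein distance

Cluster `k` is represented by the coordinate-wise median of its cells in the
embedding (medians damp outlying cells). If no embedding is supplied, PCA of
the standardized features is computed and 30 components kept (fewer if the
matrix is smaller). The default cluster-to-cluster cost is the cosine
distance between medians, bounded in [0, 2]; euclidean, manhattan and
chebyshev are available alternatives. A zero-norm median under the cosine
metric is a hard error rather than a silent fallback — it indicates an empty
or constant cluster upstream.

The sample distance is the exact optimum of the transportation LP, solved
with HiGHS dual simplex (`scipy.optimize.linprog`). One of the `2K` marginal
equalities is redundant and dropped so the constraint system has full rank.
Input distributions must sum to 1 within 1e-8 (smaller deviations are
renormalized, larger ones are errors). No entropic regularization is used
anywhere: the tests compare the solver against an independent
vertex-enumeration oracle at machine precision, which a regularized solver
would fail. Only the upper triangle of the sample matrix is solved and
mirrored. A cosine-distance-between-proportion-rows baseline
(`proportion_baseline_distance`) is provided for benchmarking; it ignores
cluster similarity entirely.

## Diffusion map and progression score

The affinity is a self-tuning Gaussian kernel on the distance matrix,

    W^s(i, j) = exp(−d(i, j)² / (ε · ρ_i · ρ_j)),

with bandwidth `ρ_i` = mean distance to the `k` nearest neighbours,
`k = max(5, ⌊√L⌋)`, and `ε` = 1 by default. Because `ρ` scales linearly
with the distances, the affinity is invariant to a global rescaling of `W`
(tested). The transition matrix `M = D⁻¹W^s` is decomposed through its
symmetric conjugate `D^{-1/2} W^s D^{-1/2}` with a dense symmetric
eigensolver; the trivial constant eigenvector (eigenvalue 1) carries no
geometry and is dropped; the next two eigenvectors, each scaled by its
eigenvalue, are the diffusion coordinates. Eigenvector signs are fixed by
making the largest-magnitude entry positive.

The trajectory backbone is deliberately simple and fully deterministic: the
minimum spanning tree of the 2-D coordinates, its diameter path as the
backbone polyline, orthogonal projection of every sample onto the polyline,
and ranking by arc length from the root end. An elastic-principal-graph
fitter could be slotted in behind the same interface; the MST diameter
reproduces path-shaped backbones without extra tuning parameters, and its
recovery of planted orders is what the tests actually verify. The root is a
sample id, or `"auto"`: with a per-sample status column the control-labeled
sample at the controls' end of the first diffusion coordinate, otherwise the
sample with the minimal first coordinate — a deterministic replacement for
visual root selection. Ranks are 1..L with ties broken by sample-id order.
Progression scores from multiple structure types measured on the same
samples (e.g. glomeruli and tubules) are combined by element-wise sum and
re-ranked.

Caveat: if the root projects into the middle of the backbone rather than an
end, samples on the far side share its low ranks; the intended use is a
root at a trajectory extreme.

## Sample clustering

The distance matrix is turned into a symmetric kNN graph (union of each
sample's `max(5, ⌊√L⌋)` nearest neighbours) with bounded edge weights
`1/(1+d)`; Leiden modularity optimization runs at a given resolution with a
fixed seed (default 0). `select_resolution` scans a grid (default 0.1..1.0)
and keeps the clustering with the highest silhouette computed directly on
the input distances, preferring the smallest resolution on ties; if every
grid point yields a single cluster the silhouette is undefined and an error
asks for a wider grid.

## Trend models

Features (gene expression per cell, cluster proportions or morphometrics
per sample) are regressed on the progression score, which is first mapped
to [0, 1] so that the Huber threshold has a stable meaning across cohort
sizes. Three families are fitted:

    x = μ + β₁ p,   x = μ + β₁ p²,   x = μ + β₁ p + β₂ p².

Fitting minimizes the Huber criterion (quadratic within δ, linear beyond;
δ = **1.35** on MAD-standardized residuals) by iteratively reweighted least
squares, tolerance 1e-8 on coefficients, at most 200 iterations. Model
quality is a modified R² in which the residual sum of squares is replaced by
the Huber penalty (computed at threshold δ·MAD), so a single outlying cell
cannot destroy an otherwise good fit. Dropout-driven zero inflation in
scRNA-seq produces exactly the one-sided heavy residual tails this
robustness targets.

**Family selection.** The three families are nested: the linear+quadratic
model always attains at least the R² of the other two, so ranking by R²
alone would always return the largest family. A family is therefore a
*candidate* only if its overall F-test (Huber-weighted sums of squares,
fitted family vs. intercept-only) **and** every non-intercept coefficient
(two-sided t-test) are significant at α = 0.05; among candidates the highest
modified R² wins, and with no candidates the family is `"none"`. The
coefficient requirement is the parsimony guard that makes correct family
identification possible; it only rejects the larger model when its extra
term is statistically indistinguishable from zero.

**Coefficient covariance.** Standard errors and the Wald covariance come
from the M-estimator sandwich formula with Huber's small-sample correction,

    V̂ = κ · (Σψ²/(n−k)) / (Σψ′/n)² · (XᵀX)⁻¹,
    κ = 1 + (k/n)·var(ψ′)/mean(ψ′)²,

where ψ is the Huber influence function at the fitted scale. The naive
alternative — reading the covariance off the final weighted-least-squares
step — systematically underestimates sampling variance and made the
downstream Wald test anti-conservative in calibration runs; the sandwich
estimator is the standard consistent choice for M-estimators and is what
the calibration tests validate.

## Wald curve test

Whether a cluster's trend differs from everything else: the family is
selected on the cluster's cells (falling back to the best-R² family when
none is significant, so the contrast is always defined), both cluster and
background are refitted with that family, and the contrast evaluates the
curve difference at `n = 100` evenly spaced points in [0, 1]:

    W = (Cᵀβ̂)ᵀ (CᵀV̂C)⁺ (Cᵀβ̂),

with the pseudo-inverse taken by eigendecomposition keeping eigenvalues
above 1e-8; the number kept is the χ² degrees of freedom (the geometric
rank is at most the number of model coefficients, so in practice r ≤ 3).
A fully singular contrast returns p = 1 with a warning. Calibration (type-I
error ≈ 0.05) and power against a 5σ curve shift are exercised by the
acceptance suite at 500 null replicates.

## Group tests

Welch's unequal-variance t-test (Satterthwaite degrees of freedom) compares
a cluster's proportion between two sample groups. Per-gene expression of one
cluster between two sample groups uses a moderated t-test: gene-wise pooled
variances `s²_g` (residual dof `n−2`) are shrunk toward a common prior
`(d₀, s₀²)` fitted by moment matching on `log s²` (digamma/trigamma
inversion, the standard empirical-Bayes variance model); the moderated t has
`n−2+d₀` degrees of freedom. When the observed log-variance spread is no
larger than its sampling noise, `d₀ = ∞` and every gene is tested against
the common variance. The implementation is verified against the reference
empirical-Bayes implementation in R to 1e-6 on a fixture. Zero-variance
genes are excluded and reported. Cell-level expression enters the test (one
observation per cell), matching how the per-cluster contrast is defined.

Benjamini–Hochberg adjustment is applied within each analysis family — all
genes of one cluster, all clusters, all covariates — never pooled across
families.

## Covariate association

Clustering × discrete covariate: χ² independence test; clustering ×
numeric: one-way ANOVA; progression × discrete: one-way ANOVA of scores by
level; progression × numeric: Spearman correlation. Single-level covariates
are skipped and reported. These tests deliberately include technical
covariates (batch, site): a technical variable more strongly associated
with the clustering than the phenotype is a red flag for artifacts.

## Evaluation metrics

ARI (permutation-model), silhouette computed directly on a distance matrix,
area under the precision-recall curve of a progression score against binary
labels, Spearman correlation against ordinal severity, and the
Friedman–Nemenyi rank test across datasets (per-dataset average ranks,
χ² with tie correction, pairwise p-values from the studentized range
distribution). Because trajectory direction is arbitrary, AUCPR evaluates
both orientations of the score and reports the better one together with the
orientation — the permutation baseline of this maximum therefore sits
slightly above the positive-class prevalence. AUCPR integration is
step-wise (average precision), not trapezoidal. The silhouette is the
standard index on [−1, 1].

## Synthetic cohorts

The generator emulates the input structure the pipeline assumes: `L = 60`
samples, `K = 5` clusters, 2000 cells per sample, a 10-dimensional
embedding with cluster centroids drawn at standard deviation 3 under a
minimum pairwise separation of 2, cells at standard deviation 0.5 around
their centroid, 50 genes with per-cluster baselines, planted polynomial
gene trends (effect 2.0), Gaussian noise (sd 0.5) and 20% dropout-style
zero inflation. Trajectory scenario: per-sample latent times are equally
spaced on [0, 1] and cluster proportions follow positive, renormalized
linear/quadratic curves of that time. Groups scenario: three groups with
rotated dominant-cluster compositions. Per-sample cluster counts are
multinomial draws, so empirical proportions converge to the planted curves
(tested at 10,000 cells). All randomness flows through a single seeded
generator; a config plus seed is byte-reproducible.

What the generator does *not* emulate — and therefore what passing tests do
not certify about real data: batch effects and integration artifacts,
cluster mis-assignment, count-distributed (negative-binomial) expression,
gene–gene correlation, uneven cell capture between conditions, and
continuous cell-state geometry within clusters. The cost matrix on real
data also inherits whatever embedding the upstream pipeline produced.

## Numerical conventions

Distribution tolerance 1e-8 with renormalization inside it; transport plans
clipped at 0 after the solve; cost matrices symmetrized and zeroed on the
diagonal against floating-point asymmetry; eigenvector signs fixed by the
largest-magnitude entry; ranking ties broken by sample-id order everywhere;
Leiden seeded (default 0) and exposed. Problem sizes in tests and in the
acceptance script (cohorts of 60 samples × 2000 cells, 500 Wald replicates,
200 transport oracle instances) were chosen as the smallest at which the
measured properties are stable across seeds.
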