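# Methods

## The problem

In integrative multi-omics studies, gene expression typically sits between an
upstream molecular measurement (here DNA methylation at q CpG sites) and a
phenotypic outcome. Because expression requires invasive tissue sampling, a
large fraction of subjects often has no expression profile at all — the
missingness is *block-wise*: a subject either has its full expression row or
none of it. Discarding incomplete subjects (complete-case analysis) wastes
most of the sample when the missing rate is high; imputing a whole expression
profile from nothing is ill-posed.

`wpomics` instead treats the two subject groups as two sources of evidence
about the same per-CpG null hypotheses and combines them through weighted
p-value adjustment. All missingness is assumed completely at random (MCAR)
with respect to (M, X, Y).

## The model

Samples are split into the complete set Z1 (n1 subjects with methylation M,
covariates X, outcome Y and standardized expression G) and the incomplete set
Z2 (n2 subjects without G); λ = n2/n is the missing rate.

**Complete-set route (integrative two-stage model).** On Z1:

    E[Y_i | G_i, X_i] = α0 + G_i'α_G + X_i'α_X            (outcome model)
    G_i'α̂_G = β0j + β_Mj M_ij + X_i'β_X + u_ij            (per-CpG model)

The first OLS fit yields the gene score s_i = G_i'α̂_G — the expression-borne
part of the outcome, with the outcome's residual noise filtered out. The
second fit regresses s on each CpG in turn; p_IG_j is the two-sided t-test
p-value for β_Mj = 0 with n1 − r − 2 degrees of freedom. The gene score is
treated as data (plug-in): the standard error deliberately ignores the
sampling error of α̂_G. Under the null this plug-in statistic is calibrated
(verified against a textbook OLS oracle and by uniformity tests); a variant
propagating the first-stage variance was evaluated and found severely
conservative (per-test level ≈ 0.002 at nominal 0.05), so it is not offered.

**Incomplete-set route.** On Z2, a marginal linear model per CpG:

    Y_i = γ0j + γ_Mj M_ij + X_i'γ_X + ε_ij

gives p_LM_j. When the two-stage model generates the data, γ_Mj = 0 is
equivalent to β_Mj = 0, so both routes test the same hypothesis.

**Cross-weighting.** Because Z1 and Z2 are disjoint, each route's p-values
are a valid independent prior for the other's. Raw weights follow
w_j = sqrt(−log10 p_j) if p_j < 0.05 (strict) else 1, then are divided by
their mean so the weight vector averages exactly 1 — the normalization that
preserves the family-wise error rate on average. The *general* scheme
adjusts the complete-set p-values with incomplete-set weights
(p1_j = p_IG_j / w*_Gj); the *reverse* scheme does the opposite
(p2_j = p_LM_j / w*_Rj). Adjusted p-values are clipped into
[floor, 1], where floor is the smallest positive normal double
(≈ 2.2e−308) so that −log10 and tangent transforms stay finite.

**Omnibus combination.** The two adjusted p-values are combined with a
Cauchy combination (ACAT) statistic:

    T_j = (1 − λ)·tan((0.5 − p1_j)π) + λ·tan((0.5 − p2_j)π),
    p_omnibus_j = 1/2 − arctan(T_j)/π.

λ is the missing rate: the scheme expected to be more informative is
up-weighted automatically. For a component p below 1e−15 the tangent is
replaced by 1/(pπ) (the float argument rounds onto π/2 there; the stabilized
form has relative error O(p)); the same guard is applied on the output side
for very large T. λ = 0 or 1 returns the corresponding component exactly.
An override of λ is available for sensitivity analysis.

**Error control.** Since the weights are already divided in, plain Bonferroni
on the adjusted vector (reject p ≤ α/q) is the weighted-Bonferroni FWER rule,
and Storey q-values give FDR control. With π0 pinned at 1 the q-values equal
Benjamini–Hochberg adjusted p-values (checked exactly against an independent
implementation); the π0 smoother (estimates π̂0(λ′) on a grid λ′ =
0.05…0.95, smoothing-spline read-out at 0.95, truncated into (0, 1]) is used
automatically only for q ≥ 100 tests — on tiny vectors (e.g. q = 5) the
smoother is unstable, so π0 = 1 is the conservative default there.

## High-dimensional expression: SVD factor reduction

When d approaches or exceeds n1 the outcome model is unfittable on raw G.
Expression is modeled as G_i = B f_i + U_i with k latent pathways, cov(f) = I.
Scores are estimated from the SVD of the column-standardized G as
F = sqrt(n1 − 1)·U_k (orthogonal columns, unit sample variance; each
component's sign is fixed so its largest-magnitude gene loading is positive).
Any invertible linear re-scaling of F leaves the fitted gene score — hence
every downstream p-value — unchanged (a column-space property, asserted
numerically in the tests), so the scaling convention is harmless.

The rank k is chosen by Wold-style speckled tenfold cross-validation: matrix
entries are partitioned uniformly at random into ten masks; per fold and
candidate k (grid 1…10), held-out entries are treated as missing and
completed by iterative rank-k SVD imputation (column-mean initialization,
alternate rank-k truncation and refill until the imputed entries change by
less than 1e−6 relative or 100 iterations); the k minimizing total held-out
squared error wins. The truncation is computed through the Gram matrix of the
short side (a projection U_kU_k'W), which equals the truncated-SVD
reconstruction at a fraction of the cost. Slow geometric convergence near the
noise floor is expected; the completion then stops at the iteration cap and
the last iterate is used, which changes held-out error negligibly.

A detectability caveat documented here because it matters for interpreting
the evaluation: under the default high-dimensional generating conditions
(n = 150, d = 1000, k = 5, 70% missing, hence n1 = 45), the per-factor signal
singular values (s² ≈ 1400–1600) of the four non-shared pathways sit at or
below the Marchenko–Pastur noise edge ((√45 + √1000)² ≈ 1469). No
reconstruction-based criterion can profit from components below that edge, so
the cross-validation selects k = 1 (the shared-covariate component) rather
than the generating 5. This is a property of the study conditions, not of the
selector: on noiseless low-rank matrices it recovers the true rank 10/10, and
it picks the correct rank on spiked matrices whose factors are above the
detection threshold. Downstream null calibration and power are insensitive to
this choice because the leading score already carries the methylation signal.

## Synthetic-data generator

Low-dimensional regime (d = 8): M (n × 5) and X (n × 2) are i.i.d. standard
normal; the first CpG is causal. Three causal genes follow
G_l = γ_0G + γ_MG,l·M_1 + 0.5·(X_1 + X_2) + ε, the other five are N(μ_0G, 1)
noise; the outcome is Y = γ_0Y + Σ_l γ_GY,l·G_l + 0.5·(X_1 + X_2) + ε, all
noise unit-variance Gaussian. High-dimensional regime (d = 1000): k = 5
pathway scores follow the same linear model, Y loads on the scores, and
G = fB' + U with B = (1/√n)·L'E for an n × d standard-normal L and E the top-k
eigenvectors of LL'.

Two deliberate conventions:

* **Heterogeneous effects.** The elements of γ_MG and γ_GY are drawn i.i.d.
  N(mean, 1) afresh per replicate (`coef_sd = 1`). A zero mean denotes a
  truly absent association (exact zero vector), so null scenarios are exact
  nulls. This heterogeneity is what produces the documented regime change —
  the general scheme wins at low missing rates, the reverse scheme at high
  ones — because replicates in which the incomplete-set route happens to
  carry the stronger marginal signal then exist. With deterministic equal
  coefficients (`coef_sd = 0`, also supported) the complete-set route's
  noise-filtered gene score dominates at every missing rate and the regime
  change disappears.
* **Intercepts at zero.** γ_0G, μ_0G, γ_0Y default to 0: every downstream
  fit carries an intercept, so location shifts cannot affect any p-value.

Missingness removes round(λ·n) whole expression rows uniformly at random
(deterministic count, so stated missing proportions are hit exactly); the
retained block is then column-standardized over the complete set (ddof = 1).

What the generator does *not* emulate: correlated CpG sites, non-Gaussian
(e.g. RNA-seq count) expression, bounded methylation β-values, informative
(MNAR) missingness, and batch or population structure. Passing tests
therefore demonstrate correctness of the machinery and its operating
characteristics under idealized Gaussian MCAR conditions, not robustness to
real-data artifacts.

## Evaluation harness

* **Scenario 1 (global null):** γ_MG = γ_GY = 0, 1000 replicates at missing
  rates 20/50/70%. FWER = share of replicates with ≥ 1 weighted-Bonferroni
  rejection; FDR = mean false-discovery proportion V/max(R, 1) under the
  q-value rule, both at α = 0.05.
* **Scenario 2 (low-dimensional power):** detection rate of the causal CpG
  over a grid of γ_MG ∈ {0, 0.1, 0.2, 0.5}, γ_GY ∈ {0.1, 0.2} and missing
  rates. The committed decision rule is weighted Bonferroni at α = 0.05 over
  the q tests; an unadjusted per-test rule is available behind a flag.
* **Scenario 3 (high-dimensional power):** d = 1000, k = 5, 70% missing,
  factor reduction in the complete-set route. The rank is cross-validated
  once on a pilot replicate per cell and cached (per-replicate reselection
  available behind `reselect_k`).

Baselines: complete-case integrative model (`ig_complete`), all-subjects
marginal linear model (`linear_all`, which ignores G and therefore produces
identical cells at every missing rate — a built-in consistency check), and
subject-space 10-nearest-neighbour imputation (`knn_impute`): a sample
missing its expression row receives the mean expression of its 10 nearest
complete samples by Euclidean distance on (M, X, Y), after which the
integrative model runs on all n subjects. Gene-wise KNN imputation is
undefined for fully missing rows; the subject-space variant is this package's
committed interpretation, so its numbers are not directly comparable to
published values obtained with gene-wise imputers. Chained-equation multiple
imputation is out of scope.

Per-replicate random streams are spawned from the master seed with distinct
keys for data generation and missingness, so (a) every method sees the same
data within a replicate, (b) baselines that ignore G see identical data
across missing rates, and (c) every report is a pure function of
(config, n_iter, seed).

Problem sizes used by the shipped acceptance runs: 1000 replicates per
missing rate for the null study, 300 per cell for the power orderings, 200
per cell plus 10 pilot rank selections for the high-dimensional study.

## Numerical choices

* OLS via dense QR; a design column whose R-diagonal falls below 1e−10 of the
  maximum raises a singular-design error naming the column.
* A fit whose residual sum of squares is below 1e−12 of the response's total
  sum of squares is degenerate: the p-value floor is returned with a flag
  rather than raising, so genome-scale loops do not abort; a constant CpG
  column yields a flagged NaN entry in the vector outputs.
* Ties in p-values are handled by stable sorting; tied p-values receive
  identical q-values.
* The weight-activation threshold (0.05) is configurable; the default is the
  published convention.

## Known limitations

* FWER/FDR guarantees of the weighting schemes are on-average (mean-1
  weights), not conditional on the realized weights.
* The ACAT combination takes exactly two components; multi-route extensions
  would need a weight vector.
* The high-dimensional rank selection is reconstruction-based and cannot see
  factors below the Marchenko–Pastur detection edge (see above).
* Covariates are passed through numerically; categorical encodings are the
  caller's responsibility.
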