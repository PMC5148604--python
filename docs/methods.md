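# Methods

## The regression model

Each feature is analyzed at the species level (replicates averaged on the
log₁₀ scale). For species values `y` and a log₁₀ life-history trait `x`,

    y = β₀ + β₁ x + ε,   ε ~ MVN(0, σ² V₀(θ)),

with four candidate correlation structures `V₀` built from the rooted,
branch-length-bearing phylogeny:

| model     | structure                                                 | free θ |
|-----------|-----------------------------------------------------------|--------|
| null      | identity (independent residuals)                          | —      |
| brownian  | `V_ij = t_ij` (shared root-to-MRCA path length)           | —      |
| lambda    | BM off-diagonals × λ, diagonal unchanged                  | λ∈[0,1]|
| ou        | `e^{−α d_ij}(1−e^{−2α t_ij})/(2α)`                        | α>0    |

The OU form is the non-stationary Hansen form (process started at the
optimum with zero root variance), chosen because it reduces to Brownian
motion as α → 0, keeping the four-way maximum-likelihood comparison a
comparison of nested/limiting structures. The stationary OU form is a
straightforward alternative but does not nest BM. The `null` structure is
plain independence; on the ultrametric unit-depth trees used throughout it
coincides with λ = 0.

β and σ² are profiled analytically, so only the correlation structure
matters for the point estimates; the reported log-likelihood is the profile
value `−n/2(log 2π + log σ̂²_ML + 1) − ½log|V₀|` with `σ̂²_ML = r'V₀⁻¹r/n`,
which is directly comparable across structures. Slope inference uses the
unbiased variance `r'V₀⁻¹r/(n−2)` and a t distribution with `n − 2` degrees
of freedom (the estimation of λ or α is not charged a degree of freedom;
with the structure known this t-statistic is exactly t-distributed, which
the test suite verifies by simulation).

Model choice is by raw maximized likelihood across the four structures, ties
resolved in the order null, brownian, lambda, ou (so BM wins an exact tie
with λ̂ = 1). An information-criterion option is deliberately not the
default. Because λ and OU both nest BM, data generated under BM are
legitimately claimed by either with λ̂ ≈ 1 or small α̂; the selected label is
not meaningful in that regime, only the implied covariance is.

### Optimization

λ is maximized on a 21-point grid over [0, 1] refined by nested vectorized
grids (bracket shrunk 20× per stage) to 10⁻⁶; α on a 20-point log-spaced
grid over [10⁻⁴, 50] per unit tree depth, refined to 1% on the log scale.
Profile likelihoods here are cheap and occasionally multimodal, which is why
grids precede local refinement. Two implementation details make the
leave-one-out screen tractable: the λ profile is computed through a one-time
simultaneous diagonalization of the BM matrix against the depth diagonal
(each candidate λ then costs O(n)), and all solve operators are cached per
exclusion subset, since the screen refits the same subsets for thousands of
features. Covariances get a relative jitter of 10⁻¹² on the diagonal before
Cholesky factorization. Exact fits (residual sum of squares below 10⁻³⁰⁰)
report the minimum positive double as the p-value rather than zero.

## The two-step verification

Step 1 refits the model selection with each single species excluded; the
exclusion minimizing the slope p names the potential outlier (ties broken by
species-label order) and that minimum is `p value.robust`. The outlier is
removed unconditionally, even when no exclusion improves on the full fit.
Step 2 excludes each remaining species in turn (n − 2 species per refit) and
reports the maximum p as `p value.max`. The evolution model is re-selected
inside every exclusion refit; freezing the full-fit structure (or the full
covariance) was implemented and measured during development and changes the
null behavior only marginally (see *Calibration* below). Exclusion subsets
use submatrices of the full-tree path-length matrices, which is exact — it
equals pruning that preserves patristic distances and root-to-tip depths.
Benjamini–Hochberg q-values are computed per trait across features for each
p column.

## Calibration of the screen (what the tests show)

Measured on 2,000 null features simulated under BM on a 15-tip unit-depth
pure-birth tree (the acceptance configuration):

- Under the **true** structure the slope p-value is exactly Uniform(0,1)
  (Kolmogorov–Smirnov p between 0.18 and 0.54 over 3×3,000 features).
- With four-way model selection, the `p value.all < 0.05` rate is 0.042–0.07
  depending on the tree (selection can shop for the structure that
  flatters the slope; at the acceptance configuration it measured 0.049).
- The robust step is strongly anti-conservative by construction:
  `p value.robust < 0.01` for ~5% of null features (a minimum over 15
  correlated leave-one-out p-values).
- The dual threshold (`p.robust < 0.01` and `p.max < 0.05`) passes 3–5% of
  null features, **not** under 1%: the second-step p-values are highly
  correlated with the first, so the max-step restores only part of the
  stringency. This holds for every variant measured (model re-selected,
  structure frozen, covariance frozen). The corresponding acceptance test
  asserts the stricter 1% expectation and fails honestly; the practical
  reading is that the dual threshold controls the per-feature error rate at
  roughly the few-percent level at n = 15, and the q-value columns — not the
  raw dual threshold — should be used for FDR statements.

## Parameter recovery

With an unstructured (iid) covariate at 50 tips, the λ̂ estimator matches the
standard references (identical data given to `nlme::gls(corPagel)` agrees to
4 decimals where its optimizer converges; `phytools::phylosig` medians agree
to ~0.03). Boundary values are recovered cleanly (median λ̂ = 0.0 at λ = 0,
1.0 at λ = 1) and the planted slope is recovered with bias ≈ 0.005. At
λ = 0.5 the ML estimator is biased low on these trees — median λ̂ 0.31–0.45
across pure-birth trees, tree-shape dependent — a finite-sample property
shared by the reference implementations, so the ±0.1 recovery band holds on
some trees and fails on others. The recovery experiment deliberately uses an
iid covariate: when the covariate itself evolves on the tree, the regression
absorbs part of the phylogenetic signal and the residual-λ truth is no
longer the simulated value; that confounded design costs a further ~0.05
downward shift.

## Synthetic data: what it emulates, and does not

The generators mirror the structure of the fibroblast study design: 15
species on an ultrametric pure-birth tree scaled to unit depth (so λ and α
are comparable across simulations); adult weight log-uniform over 10 g–20 kg
with maximum lifespan and female time to maturity following the allometric
laws `4.88·AW^0.153` (years) and `78.1·AW^0.217` (days) times a lognormal
deviate whose log evolves by BM (tip sd 0.4); expression on the log₁₀ scale
with BM residual sd 0.2 (≈1.6-fold between-species spread); 10% of features
associated with slope ±N(1.0, 0.2) per log₁₀ trait unit (several-fold
change across a ~15× lifespan range — the strong-hit regime the dual
threshold is meant to retain; a priori, at n = 15 this gives slope
t-statistics ≳ 5 after worst-case single-species removal, hence the ≥80%
dual-threshold recall the acceptance suite measures); two replicates per
species with iid log-scale noise sd 0.1 (replicate clustering without a
published variance-component estimate); negative-binomial counts
(dispersion 0.1) with planted filter violations; lognormal metabolite
intensities in three acquisition modes whose per-(mode, sample) batch factor
multiplies the internal standard and thus cancels exactly under
internal-standard division.

What passing on these data does **not** show: robustness to misspecified
trees or branch lengths, non-Gaussian expression noise, correlated
replicate structure, mean-variance coupling in counts beyond the NB model,
informative (non-MCAR) metabolite missingness, or measurement error in the
traits themselves. All generators run on numpy's PCG64; a fixed seed is
bit-reproducible.

## Normalization choices

The >5%-of-a-sample count rule is applied per sample (violation in any one
sample removes the feature) in a single pass against the input column
totals, matching one-shot removal; on realistic matrices a second pass is a
no-op, though a matrix dominated by one gene could in principle expose a
new violation after removal. TMM uses the method's standard trims (30% on
M, 5% on A, both tails), precision weights from the binomial variance
approximation, the 75th-percentile rule for the reference column, and
factors rescaled to product 1. Quantile normalization maps each column onto
the mean of the sorted columns, ties receiving the mean of the reference
quantiles they span — with no missing values this is exact (identical
sorted vectors). Metabolite matrices keep missing cells masked: quantile
pools simply exclude them (each column is mapped through the average
empirical quantile function), rather than imputing. Counts are offset by
+0.5 before log₁₀ (flag-controlled); standardization uses the sample (n−1)
standard deviation; library-size division precedes the log.

## Phylograms and auxiliary analyses

Neighbor joining uses the Studier–Keppler Q-criterion with ties broken by
the smallest row/column index pair; negative branch estimates are clamped to
zero with the deficit moved to the sibling branch, and on additive inputs
the tree reproduces the distances exactly. Bootstrap resamples features
(rows) because the tree's taxa are the samples; supports are fractions of
replicates containing each bipartition of the point-estimate tree.
Outgroup rooting is available upstream of plotting but off by default.

The bird/primate amino-acid regression fits group intercepts and
group-specific slopes for log lifespan against a metabolite level
(`F = [(RSS_red − RSS_full)/2]/[RSS_full/(n−4)]`), with significance from a
within-group permutation of metabolite values (B = 10,000 by default,
add-one p-value) — group lifespans stay fixed, so the null preserves the
group structure. Natural log is used for lifespan; the base only shifts
coefficients, never F. When several features annotate one metabolite, the
feature most correlated with lifespan is used.

Probit LD50 fits binomial maximum likelihood with a probit link on linear
dose (a log₁₀-dose flag serves glucose-withdrawal ED50s), reports
`LD50 = −a/b` and a delta-method standard error, and raises a
non-identifiability error on constant outcomes or flat fits.

Pathway enrichment keeps sets with 5 ≤ size < 100 after intersection with
the universe, reports the upper-tail hypergeometric p (`P(X ≥ k)`), the
sample odds ratio with 0/0 flagged as infinite, and the expected overlap
`nK/N`. Fisher's overlap test is the conventional exact two-sided rule
(sum of tables no more probable than the observed one). The gene-category
machinery expects user-supplied GMT files; no external annotation service
is queried.

## Problem sizes

The default test suite and the acceptance script size their simulations to
single-CPU desk scale: 2,000 features for null calibration, 500 per λ value
for recovery, 500 metabolites × B = 1,000 permutations, 200 Monte-Carlo
dose-response panels, and a 200-gene end-to-end screen. These sizes put
Monte-Carlo standard errors well inside the asserted bands; the library
itself has no size-dependent switches.
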