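# Methods

## Model

The package works in the centered log-ratio (CLR) representation of
compositional data.  A count row w_i is closed to a composition
x_ij = (w_ij + c) / Σ_l (w_il + c) with pseudo-count c (default 0.5,
added to every entry so the map is smooth and zeros are cleared), then
mapped to z_ij = log(x_ij / gmean(x_i)).  CLR rows sum to zero, which is
why the regression coefficients carry a zero-sum constraint: the model
is invariant to the arbitrary scale of the underlying counts only on
that hyperplane.  The response model is linear-Gaussian,
y = β₀ + Zβ + ε, with the intercept absorbed by centering y and the
design columns (never penalized, never constrained).  Optional
covariates (e.g. dietary intake) enter as appended unpenalized columns
excluded from the constraint and from all groups.

## Tree groups

Each internal node v of the taxonomy contributes one group: the
membership vector m_v over the p leaves, penalized as ‖β ∘ m_v‖₂
divided by the subtree size ‖m_v‖₁.  The size divisor (rather than the
more common √size multiplier) deliberately damps large, uninformative
groups — the root group contributes ‖β‖₂/p, a near-negligible global
shrinkage — while small genus-level groups act strongly; a
`weight_mode="sqrt_size"` switch is available.  Conventions adopted
where the design was genuinely open:

- the root group is included by default (`include_root=True`); it is one
  internal node like any other, and excluding it is configurable;
- internal nodes with identical leaf sets (unary rank chains such as a
  family containing a single genus) collapse to one group attributed to
  the deepest rank, because duplicated groups would silently multiply
  the penalty weight;
- singleton internal nodes (a lineage tail ending at one leaf) are
  dropped at parse time: they duplicate the leaf's L1 term;
- blank taxonomy labels become placeholder nodes scoped by their lineage
  prefix, never merged across parents.

Group leaf sets of a tree are laminar (pairwise nested or disjoint);
this is validated at construction and is what licenses the exact
proximal operator below.

## Knockoffs

Knockoff copies Z̃ are drawn under a multivariate normal model for the
CLR rows — the representation is chosen precisely because CLR data are
approximately Gaussian.  The fitted covariance of exact CLR data is
singular (rows sum to zero), so shrinkage toward a scaled identity is
mandatory, not cosmetic: intensity is Ledoit-Wolf by default, with a
floor pushing the minimum eigenvalue to at least 1e-8 times the mean
diagonal.  The decorrelation vector s is solved on the correlation scale
— equicorrelated (s_j = min(2λ_min, 1), the deterministic default) or a
coordinate-ascent maximization of Σ s_j under the positive-semidefinite
feasibility constraint 2Σ − diag(s) ⪰ 0 (`method="sdp"`), each
coordinate step using its exact Schur-complement bound.  Sampling uses
the Gaussian closed form of the sequential conditional independent
pairs construction,
Z̃_i | Z_i ~ N(Z_i − diag(s)Σ⁻¹(Z_i − μ), 2diag(s) − diag(s)Σ⁻¹diag(s)),
with any roundoff-negative eigenvalues of the conditional covariance
clipped at zero.  Knockoffs are generated once per analysis from a
single integer seed stored in the result, and the augmented tree reuses
the original internal nodes with memberships duplicated over the
knockoff half (weights double).

## Solver

The estimator is a two-block ADMM.  Block one minimizes the quadratic
loss under the zero-sum equality constraints via a KKT linear system,
LU-factorized once per penalty level and re-factorized only when the
ADMM step size ρ changes (ρ starts at 1 with 2×/÷2 residual balancing
every 10 iterations; over-relaxation α = 1.7).  Block two applies the
penalty's proximal operator *exactly*: for laminar groups, the prox of
τ(‖·‖₁ + Σ_v ‖· ∘ m_v‖₂/w_v) is the composition of per-group
soft-thresholdings applied from leaves to root (L1 first, then groups
by ascending subtree size).  The test suite certifies this against a
consensus-ADMM oracle with duplicated group variables, and certifies
whole-fit optima against an independent SLSQP solve of the convex
program.

Numerical conventions: convergence at relative primal/dual residuals
below 1e-6 (absolute floor 1e-9) *and* constraint-block sums below
1e-6, capped at 10 000 iterations with a warning on non-convergence;
coefficients below 1e-8 in magnitude are reported as exact zeros (this
defines the support for BIC and the selection rates); the objective
trace records the best objective seen so far, so it is non-increasing
by construction; CLR columns are not standardized — their scale is
meaningful — though the design is column-centered for the intercept.
λ_max is computed from the gradient at zero of the centered data (an
upper bound under the constraint, so the null model is guaranteed
there); the default path takes 50 log-spaced values down to
0.001·λ_max, fitted warm-started from sparse to dense, with BIC
n·log(RSS/n) + K̂·log n computed on the penalized (augmented)
coefficients — K̂ counts both halves, matching the stacked coefficient
vector the fit actually produces — and ties broken toward the sparser
model.  λ is tuned once on the augmented problem; W statistics come
from the single fit at λ_opt.

The selection threshold implements the plain knockoff criterion (no +1
in the numerator); a `plus=True` flag provides the conservative
variant.  The constrained OLS refit used by the resampling protocol
solves its KKT system in closed form, returns zero (with a warning)
when fewer than two taxa are selected, and ridge-stabilizes with 1e-8
on singular systems.

## Synthetic data

The generator emulates 16S count data: per-sample proportions from a
Dirichlet with mean π and overdispersion θ, multinomial counts at a
sequencing depth drawn uniformly from [5000, 10000] (real studies have
uneven depth; the law is configurable).  Default parameters are
synthetic stand-ins for a fitted real-data model: log-normally dispersed
mean proportions (σ = 2, giving the heavy-tailed few-dominant/long-rare
profile of real communities) and θ = 0.02, typical of 16S data.  A
method-of-moments estimator (`estimate_dm_parameters`) lets users fit π
and θ from their own count table instead.

Two fixed coefficient layouts drive the benchmark response
y = Zβ + N(0, 1): a tree-aligned layout whose 12 nonzero coefficients
(magnitudes 0.5–2, summing to zero) sit inside a few subtrees, and a
dispersed layout whose 12 nonzeros are scattered across the tree.  The
bundled p = 60 tree is **synthetic**: a four-level laminar hierarchy
with genus groups of 2–5 leaves, built so the tree-aligned layout's
signal set is exactly a union of genus groups; for larger p a seeded
random recursive partition is used.  Benchmarks default to n = 200,
p = 60, 20 replicates (the package's desk-scale choice; the protocol
supports 100), with per-replicate seeds spawned from a master seed so
any replicate is reproducible in isolation; failed replicates are
recorded and excluded from means.  An effect-size sweep multiplies the
layouts by nine equally spaced factors from 0.2 to 1 and reports mean
F-scores (20 replicates per point).

The half-sample resampling protocol trains each method on a random half
of the samples.  Methods whose fitted coefficients predict directly
(tree lasso, compositional lasso) score MSPE on the other half;
knockoff-based methods — whose augmented coefficients are not a
prediction model — refit a zero-sum-constrained OLS on the selected
taxa using 80 % of the held-out half and score MSPE on the remaining
20 %, with an intercept-only fallback (flagged) on empty selections.
Taxa selected in at least 10 % of replicates form the stable set.
Predictions include the centered model's intercept.

## What the synthetic data do and do not show

The generator reproduces compositionality, heavy-tailed abundances,
overdispersion, uneven depth and tree-clustered signals.  It does not
reproduce real-data features such as taxon-taxon ecological
correlations beyond the logistic-normal-like structure induced by the
Dirichlet, zero-inflation in excess of the DM, non-Gaussian responses,
or a real taxonomy's shape; passing benchmarks therefore demonstrate
correctness and calibration of the machinery under the stated model,
not performance guarantees on any particular real dataset.  Two known
behaviors observed with the bundled generator: the BIC applied to
penalized estimates has a shrinkage bias that pulls the plain tree
lasso toward dense solutions, so its advantage over the compositional
lasso shows at matched penalty levels but can vanish after BIC tuning;
and with very weak effects the knockoff contrast dilutes power, so the
knockoff variants lose F-score at the low end of the effect-size sweep.

## Limitations

- Knockoffs assume approximate multivariate normality of CLR rows;
  strongly non-Gaussian compositions call for other generators.
- Error control is empirical here; the plain (non-plus) threshold does
  not carry the finite-sample FDR guarantee of the conservative
  variant.
- One shared λ governs the L1 and group terms; a two-λ grid is out of
  scope.
- Selection is at the leaf (OTU) level only; internal nodes shape the
  penalty but are never themselves selected.
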