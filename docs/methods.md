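# Methods

## Model and estimand

A finite population of N units is partitioned into L×M rectangular strata by
cut points on two auxiliary variables, a = x₁,₀ ≤ … ≤ x₁,L = b and
c = x₂,₀ ≤ … ≤ x₂,M = d. Under stratified SRSWOR the mean estimator has
variance Σₕₖ (1/nₕₖ − 1/Nₕₖ) W²ₕₖ S²ₕₖ. The study variable is linked to the
auxiliaries by a linear superpopulation model y = a₁ + a₂x₁ + a₃x₂ + e with
E(e|x₁,x₂) = 0 and V(e|x₁,x₂) = η, giving the model-implied stratum variance
S²ₕₖ = a₂²σ²ₕₖ,ₓ₁ + a₃²σ²ₕₖ,ₓ₂. The error variance η is *excluded* from this
expression by default: η contributes the same Σ W²ₕₖ η/nₕₖ-type floor however
the boundaries are drawn near the optimum, and the design objective targets
the systematic part. `include_error_var=True` adds η under the square root
for users who want the full model variance.

Given per-unit stratum costs Cₕₖ, overhead C₁ and budget C, the Lagrangian
allocation nₕₖ ∝ WₕₖSₕₖ/√Cₕₖ spends C − C₁ exactly and attains
V_opt = (Σ WₕₖSₕₖ√Cₕₖ)²/(C − C₁) − Σ W²S²/Nₕₖ. Ignoring the FPC (the
package reports FPC-ignored variances throughout; per-stratum population
counts are used only to clip infeasible allocations), minimizing variance is
equivalent to minimizing the cost-weighted Neyman sum Σ WₕₖSₕₖ√Cₕₖ, which is
the objective every optimizer in this package minimizes.

## Cell moments

The two axes are treated as independent, so every cell weight factorizes
into one-dimensional masses and the per-axis means/variances are truncated
marginal moments. Analytic forms:

- uniform on [A, B]: mass (hi−lo)/(B−A), variance width²/12;
- standard power δx^(δ−1)/θ^δ: raw moment of order k over [l, u] is
  δ(u^(δ+k) − l^(δ+k))/((δ+k)θ^δ);
- Cauchy with location θ′, scale t: with u = (x−θ′)/t, the primitives are
  ∫u/(π(1+u²)) = log(1+u²)/(2π) and ∫u²/(π(1+u²)) = (u − arctan u)/π.

The truncated Cauchy is **not renormalized** by default: the full-line
density is integrated over the cell, so weights on [0,1]² with a power
second axis sum to arctan(1)/π = 1/4. This matches the closed-form cell
weight W = P₁P₂/(πθ^δ), P₁ = arctan(x₁ₕ) − arctan(x₁,ₕ₋₁),
P₂ = x₂ₖ^δ − x₂,ₖ₋₁^δ; a common mass factor rescales the objective without
moving its minimizer. `normalize=True` gives a proper truncated density.

Every analytic moment is validated against nested adaptive one-dimensional
quadrature (scipy `quad`, absolute tolerance 1e−10) — the ground-truth path
kept alongside the fast path and exercised in the tests (agreement to 1e−8
relative on random cells). Thin-slice cancellation in E[x²] − m² is clamped
at zero.

Empirical cells use half-open membership [lo, hi), upper-closed on the last
stratum of each axis, so a partition assigns every unit exactly once.
Variances use the Nₕₖ − 1 divisor; cells with Nₕₖ ≤ 1 contribute zero
variance rather than erroring, so the optimizer can probe tight boundaries.

## Boundary optimization

Widths on each axis are discretized into `grid_points` equal steps (default
200 per axis; the fine-grid reference run uses 1000). A forward Bellman
recursion over cumulative width solves each axis exactly on its grid:
ψₕ(r) = min over the previous cumulative width r′ of ψₕ₋₁(r′) + gₕ(r′, r),
with stage costs gₕ allowed to depend on the stratum index (row-dependent
unit costs). Complexity is O(L·G²) with all stage tables vectorized;
zero-width strata are permitted (weight-0 cells contribute 0) and duplicate
cuts can be collapsed afterwards.

The bivariate objective couples the axes through
√(a₂²σ²₁ₕ + a₃²σ²₂ₖ)·√Cₕₖ, so a single separable DP is not exact. The
bivariate solver alternates exact axis-wise DP sweeps — re-optimizing one
axis globally while the other axis's cuts are fixed — from an equal-width
start, stopping when a sweep improves the objective by less than 1e−10 or
after 20 sweeps. The result is a coordinate-wise optimum on the grid. An
exhaustive enumerator over all monotone cut-index combinations (budget-capped
at 10⁶ evaluations, lexicographically smallest tie-break) certifies that the
alternating scheme reaches the global grid optimum on every small instance
tested (2×2 on 20-step grids; univariate instances up to L = 4 on 40-step
grids). Ties between symmetric optima are resolved deterministically
(smallest cumulative-width index), so repeated runs are bit-identical.

## Allocation and rounding

Budget mode implements the Lagrangian allocation; fixed-total mode uses the
same W·S/√C shares normalized to the requested Σ nₕₖ (with equal costs this
is Neyman allocation). Real allocations are rounded by largest remainder
after rescaling to the stated total, with a min-1 rule for every stratum
with positive real allocation and row-major tie-breaks; `floor_repair`
(floor + min-1) is available when a hard budget must not be exceeded. When
nₕₖ would exceed the stratum population Nₕₖ, it is clipped at Nₕₖ and the
surplus re-spread over the unclipped strata, iterated to a fixpoint.

## Comparators and the common metric

The benchmark scores boundary rules on one metric, (Σₕ WₕSₕ)² — the
equal-cost, FPC-ignored optimum-allocation variance numerator computed from
the sample moments of the induced strata. This definition is the package's
own (no canonical formula exists for cross-method comparison at unspecified
n); consequently only orderings and trends across methods are asserted,
never externally printed values.

- cum-√f: default bin count min(round(√n), 100).
- geometric: requires a strictly positive minimum; raises otherwise.
- Lavallée–Hidiroglou/Kozak: boundaries restricted to sorted-sample
  positions (finite search space); seeded random search from the cum-√f
  cuts, accepting only improvements, stopping after 200 consecutive
  non-improving proposals (maximum step n/100 positions).
- mathematical-programming DP: the same width-grid DP at 100 grid steps.
- proposed: the width-grid DP at 200 steps, a strict refinement of the
  100-step grid.

Before scoring, every comparator's cuts are snapped to the proposed method's
grid so all methods compete on one finite boundary space; the proposed DP is
the global optimum of that space, which guarantees (and the tests verify)
the dominance ordering, and grid refinement guarantees proposed ≤ the
coarse-grid DP.

## Synthetic study conditions

- Benchmark: n = 10,000 draws from uniform(0.002, 1.92), strata counts
  L = 2..6, 20 seeded replications in the acceptance checks.
- Application generator: 569 records emulating a tumour-morphology table —
  x₁ (mean radius) uniform on (6.981, 28.11), x₂ (mean texture) uniform on
  (9.71, 39.28), y = −5.7899 + 6.8643·x₁ + 0.0406·x₂ + N(0, 2²). The ranges
  match published summaries of the diagnostic features; the noise SD of 2
  keeps the perimeter–radius relation as tight as in the real table
  (R² ≈ 0.996) while leaving the coefficient standard errors non-degenerate.
  The generator draws axes independently, unlike the real data where radius
  and texture are mildly correlated, and its uniform marginals lack the
  right skew of real morphology measures — passing tests therefore
  demonstrate the pipeline contract (partitioning, allocation totals,
  coefficient recovery), not distributional realism.

The optimizer itself is deterministic; all stochastic components (population
draws, Kozak search) take explicit seeds, and every pipeline records its
config, seed and version in the report's provenance block.

## Reference 2×3 example

The bundled worked example (standard Cauchy × power δ = 3, θ = 1 on [0,1]²,
costs 1..6 row-major) requires slope values; the package documents and uses
a₂ = a₃ = 1. On a 1000-step grid the oracle-certified optimum has interior
cuts 0.601 on the Cauchy axis and (0.747, 0.953) on the power axis with
objective 0.06782. A previously published layout for this design reports
(0.5621; 0.2794, 0.7948) with value 0.000127; that solution evaluates to a
*larger* value (0.0800) of the objective defined here, and its printed value
is not reproducible from first-principles cell variances, so the package
reports its own certified optimum and the comparison rather than adopting
the published numbers.

## Limitations

- Only independent axes (no copulas); supports must be finite.
- The bivariate solver guarantees a coordinate-wise grid optimum; global
  optimality is certified only where exhaustive enumeration is feasible.
- Boundaries live on the width grid; continuous refinement (derivative
  conditions) is out of scope.
- The empirical bivariate optimizer uses independent marginal moments for
  the DP sweeps; the final report recomputes every cell from the true paired
  sample, so reported weights/occupancies are exact even when the marginal
  approximation guided the search.
- Heteroscedastic or nonlinear superpopulation models are not supported.
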