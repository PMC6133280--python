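# Methods

## Model

`spacc` detects multi-subject genomic regions by clustering *probes*
(columns) of a subjects-by-probes matrix `X ∈ R^{n×p}` under a chain
fusion penalty.  Per chromosome it solves the convex problem

    minimize_U  ½‖X − U‖_F²  +  γ Σ_{i=1}^{p−1} w_i ‖U_{·i} − U_{·i+1}‖₂

The group (ℓ₂) penalty on adjacent-column differences drives exact
equality of neighboring centroids as γ grows; a maximal run of equal
columns is a genomic region, shared by all subjects.  Restricting the
penalty to adjacent pairs (rather than all pairs, as in generic convex
clustering of observations) is what guarantees spatially contiguous
regions.  The problem is strictly convex in U, so every solver run
reaches the same global solution.

Spatial weights are distance-decayed, `w_i = exp(−σ d_i)` with `d_i` the
basepair gap between probes i and i+1.  The decay rate is a
technology-level constant: `σ = 1e−5 /bp` for CNV log-ratios (copy
number changes span megabases) and `σ = 2e−4 /bp` for methylation
beta-values (co-methylation is confined to CpG-island-scale
neighborhoods).  Weights below `weight_floor` (default 1e−3) are set to
exactly zero; each zero gap makes the penalty separable there, so the
chain splits into independent subproblems solved in isolation.  At the
methylation decay rate the default floor severs gaps longer than
~34.5 kb.  Chromosome boundaries are infinite-distance gaps and always
split.  The floor value itself is a package choice — the region
structure is insensitive to it because weights that small could only
fuse gaps the data would anyway keep apart.

## Optimization (AMA)

With the auxiliary variable `V_{·i} = U_{·i} − U_{·i+1}` and duals Λ, the
alternating minimization algorithm iterates

1. `U = X + [Λ, 0] − [0, Λ]` (closed form; boundary columns get a single
   dual term),
2. `V_{·i} = (1 − (γ w_i/ν)/‖g_i‖)₊ g_i` with
   `g_i = U_{·i} − U_{·i+1} − Λ_{·i}/ν` (group soft-threshold),
3. `Λ_{·i} += ν (V_{·i} − U_{·i} + U_{·i+1})`.

AMA is proximal gradient ascent on the dual, whose smooth part has
Lipschitz constant `λ_max(DDᵀ) < 4` for the chain difference operator D;
the default step `ν = 0.25` is therefore always stable.  Convergence is
declared when `max(relative U change, max_i ‖V_{·i} − U_{·i} +
U_{·i+1}‖₂) ≤ tol` (default 1e−6, cap 10,000 iterations).
Initialization: `U⁰ = X`, `Λ⁰ = 0` (or warm-started duals).

Three numerical devices speed this up without changing the fixed point:

* **Nesterov acceleration with gradient-based adaptive restart** of the
  dual sequence (default on; `accelerate=False` recovers plain AMA,
  whose primal objective trace is monotone after burn-in and is what the
  monotonicity test exercises).
* **Closed-form full-fusion shortcut**: the fully fused solution is the
  per-subject segment mean with duals `Λ_k = Σ_{j≤k}(X̄ − X_{·j})`; it is
  dual-feasible iff `γ ≥ γ_max = max_k ‖Σ_{j≤k}(X_{·j} − X̄)‖₂ / w_k`,
  which is therefore the exact full-fusion point (also used to scale the
  γ grid).  When feasible it is returned directly.
* **Warm starts** along the γ grid and across the missing-data outer
  loop.
* The iteration kernel is compiled (numba) in probe-major layout; a pure
  numpy reference path implements the identical updates and the two are
  tested for agreement.

## Missing values

With missing cells M the loss runs over observed cells only — still
convex.  The majorization-minimization surrogate adds
`½ Σ_{(i,j)∈M} (U_ij − U_ij^k)²`; minimizing it is a complete-data solve
on the working matrix `T` whose missing cells hold the current
centroids.  Alternating the fill-in and the solve yields a
non-increasing sequence of true objective values converging to the
global solution; the missing entries of the final `U` are model-based
imputations.  The first fill is the per-subject mean of observed values
(any start reaches the optimum; this one is close and cheap).  Outer
loop stops at relative objective change 1e−7 or 100 iterations.
Masks are cell-level — any pattern is accepted, which cross-validation
relies on.

## Cross-validation and thresholding

The observed cells are partitioned uniformly at random into K (default
5) near-equal folds.  For each fold and each γ (ascending, warm-started)
the missing-data problem is solved with the fold's cells additionally
masked, and scored by the mean squared error of the fitted centroids at
the held-out cells.  `γ*` minimizes the fold-averaged MSE; ties break
toward larger γ.  The default grid is 15 log-spaced values on
`[1e−3·γ_max, γ_max]` with `γ_max` the adaptive full-fusion point.  The
CV refits use looser solver tolerances (`cv_tol = 1e−3`,
`cv_outer_tol = 1e−4`) than the final fit; MSE differences between
neighboring grid points are orders of magnitude larger than the solver
error, and the selected `γ*` was verified to be invariant down to
`cv_tol = 1e−5` on both data types.

Held-out-cell CV systematically under-fuses: predicting a held-out cell
rewards local interpolation, so `γ*` sits below the region-recovering
range whenever within-region variation is spatially smooth.  The fit at
`γ*` is therefore post-processed by element-wise thresholding of V at
the universal level

    λ = sqrt(log(p) / n) · σ̂        (natural log)

Entries with `|V_ij| < λ` are zeroed (strict inequality); probes i, i+1
fuse iff the whole thresholded column is zero and `w_i > 0`.  Requiring
the entire column to vanish makes the rule conservative: a single
subject with a real jump preserves the boundary.

**Choice of σ̂.**  The threshold must separate between-region jumps from
within-region variation in V.  Because fusion needs *every* entry of a
column below λ, λ has to sit above the extreme within-region deviations
— a scale set by the spread of the data, not by the (possibly much
smaller) local noise: under strong spatial correlation adjacent-difference
noise estimates collapse toward zero while within-region columns still
carry drift-scale entries, and no threshold proportional to the local
difference scale can zero them.  The default estimator is therefore the
robust data spread,

    σ̂ = median(|X − median(X)|) / 0.6745,

computed over observed cells within weight segments (per problem, i.e.
per chromosome).  Between-region jumps are order-σ̂ by construction,
while `sqrt(log p / n)` shrinks the level with subject count, so
boundaries survive whenever any subject separates the regions.  For
piecewise-constant signals with a dominant iid noise floor, the
classical difference-based estimate
`σ̂ = median|X_{i,j+1} − X_{i,j}| / (0.6745·√2)` is available as
`sigma_method="mad_diff"`; it is calibrated for the true noise sd in
that regime (tested) but under-thresholds when neighboring probes are
strongly correlated.

## Synthetic data generators

All generators draw one RNG substream per subject (growing n never
changes earlier subjects); global draws use a dedicated substream.
True layouts are synthetic: `make_layout` tiles p probes into contiguous
regions with sizes drawn from a range (`n_regions` is a minimum; sizes
are drawn until p is covered and trimmed exactly), small within-region
spacing and larger inter-region gaps.  The real studies seed layouts
and baselines from observed segmentations; the synthetic stand-ins are
cleaner — boundaries coincide with genuine generative breaks — so
recovery scores here can exceed those reported on data-derived truths.

* **CNV**: `X_ij = μ_j + s_{i,r(j)} m_{i,r(j)} + ε_ij`, with
  `s ~ Bernoulli(q)` per subject/region, `m = ±Uniform(a, b)` (sign
  equiprobable — the sign law is a package choice), `ε ~ N(0, σ)`,
  baseline μ = 0.  Regimes: (a, b) = (0.2, 0.4) easy / (0.05, 0.3) hard
  at σ = 0.1; q = 0.7 / 0.5.
* **Methylation**: latent `z_i ~ N_p(0, Σ)` with
  `Σ_ij = exp(−d_ij/σ_w)` within regions, `exp(−d_ij/σ_b)` between;
  `X = Φ(z)` has uniform marginals in (0, 1).  Scenarios fix
  σ_w = 100 kb and σ_b = 0.01/0.1/1 kb (high/medium/low separation).
  The blockwise Σ need not be PSD; eigenvalues are clipped at 1e−8 and a
  warning is logged if any entry moves by more than 0.05.  Note this
  model has **no iid noise floor** — adjacent within-region probes are
  nearly exchangeable copies — which is exactly the regime where CV
  under-fuses and thresholding carries the region detection.
* **rEWAS**: per-subject region means `m_ig ~ Beta(2, 2)`; probes
  `X_ij ~ Beta(κ m, κ(1−m))` so `E[X] = m` (κ = 20 by default; the
  generative constraint fixes only the mean, κ sets within-region probe
  noise sd ≈ 0.11 at m = 0.5); response
  `y = Σ_l β_l m_{i,g_l} + ε`, `β_l ~ N(β_seed, β_seed)` (second
  parameter read as a variance), causal regions sampled without
  replacement.  Reference scale n = 94, p = 23,515; the studies here run
  p = 2,000.

What passing these simulations shows — and does not: the generators
produce exchangeable-within-region signals with clean boundaries and no
batch structure, probe-specific biases, or boundary ambiguity.  Real
array data adds all of those, so simulation recovery rates are upper
bounds, not forecasts.

## Scoring

Partition agreement uses pair-counting indices (Rand, adjusted Rand,
Jaccard) from the 2×2 pair table and the Variation of Information
`VI = H(P) + H(Q) − 2I(P, Q)` in nats (natural log; a `vi_base` option
rescales).  Association recovery is scored from the probe point of view
(probes inside significant regions vs probes inside causal regions) and
the region point of view (a significant estimated region is a true
discovery when more than half its probes — configurable — lie inside a
single causal region).  With zero discoveries FDP is 0; with empty
causal truth TPR is returned as 0 and flagged undefined.

The association scan itself is ordinary least squares of the response on
(intercept, feature) with a two-sided t-test on the slope,
Benjamini-Hochberg step-up at the requested FDR (inclusive boundary);
zero-variance features get p = 1 and a flag.

## Study drivers and problem sizes

`spacc.studies` reruns the simulation designs end to end at scaled-down
sizes chosen to keep a full sweep within a desktop budget: CNV regimes
at n = 40, p = 1000, 10 replicates; methylation scenarios at n = 100,
p = 1000, 10 replicates; the rEWAS power comparison at n = 94, p = 2000,
3 replicates with the response regenerated at noise sd
σ ∈ {0.25, 0.5, 1.0} (an SNR sweep over one shared, response-free
segmentation); the null-FDR study at 200 replicates.  CV uses 5 folds
over the 15-point grid throughout.

## Known limitations

* Single-chain fusion only: no general-graph penalties, no ADMM variant.
* γ selection is per chromosome; no information is shared across
  chromosomes.
* The universal threshold assumes the data spread is a sensible jump
  scale; data whose regions differ by much less than the overall spread
  (e.g. one faint segment among strong ones) may be under-split.
* No uncertainty quantification on imputed cells or region boundaries.
* Beta-values are fit on their raw scale; no logit transform is exposed.
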