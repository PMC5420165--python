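# Methods

## Scope and model class

`identikit` analyses the practical (a posteriori) identifiability of
deterministic kinetic models

```
dx/dt = f(x, u, θ),   y = g(x, θ),   x(t0) = x0(θ),   θmin ≤ θ ≤ θmax,
```

where `x` are states (typically concentrations), `u(t)` piecewise-constant
stimuli, `θ` positive kinetic parameters and `y` the observables actually
measured.  Practical identifiability asks whether `θ` can be determined with
precision from the available noisy, discrete data — a stronger requirement
than structural identifiability, which only inspects the equations.  The two
failure modes addressed are (1) parameters with negligible influence on the
observed outputs and (2) interplay: groups of parameters whose effects on
the outputs can compensate each other.

Models are held symbolically (sympy) so that exact partial derivatives are
available for the sensitivity equations and for the structural network
export.  Integration uses `scipy.integrate.solve_ivp` with LSODA and is
restarted at every stimulus breakpoint, so discontinuous inputs are handled
exactly.  Defaults are rtol 1e-8 / atol 1e-10; these are deliberately tight
because the sensitivity systems amplify integration error.  Two
self-consistency properties are enforced by tests: simulation is bitwise
deterministic at fixed tolerances, and refining the tolerances tenfold moves
trajectories by less than the coarser tolerance.

## Calibration

Parameters are estimated by minimizing the weighted least-squares cost

```
Q_LS(θ) = Σ_i w_i (y_i(θ) − ỹ_i)²        (i runs over all N_D records)
```

plus a Tikhonov penalty `α·Γ(θ)`, `Γ(θ) = (θ−θ_ref)ᵀWᵀW(θ−θ_ref)`.  The
default `α = 0.1` encodes weak prior knowledge; `W` defaults to the diagonal
`1/max(|θ_ref|, ε)` so the penalty acts on relative deviations.  The role of
regularization is to combat ill-posedness and overfitting, not to improve
the fit: at equal budget a regularized estimate should never reach a lower
`Q_LS` than an unregularized one, and the acceptance suite checks exactly
that.

The optimizer is a hybrid in the scatter-search family: a Latin-hypercube
initial population, a reference set (default 10 members) kept by quality and
diversity, random pairwise combination of members, and periodic local
refinement of the best member by a bounded trust-region least-squares solve
(`scipy.optimize.least_squares`, TRF).  The Tikhonov term is carried as
extra residual rows `√α·W(θ−θ_ref)` so the local solver sees the full
objective in least-squares form.  Stopping is by objective-evaluation budget
rather than CPU time, for reproducibility; every random draw flows from a
single integer seed.  An optional log10 parameter transform is available for
rate constants spanning decades; the penalty always acts on the natural
scale.

## Sensitivity analysis and the influence filter

Output sensitivities `s_i = ∂y/∂θ_i` are computed from the forward
sensitivity equations: the state equations are augmented with
`dX_i/dt = (∂f/∂x)X_i + ∂f/∂θ_i`, `X_i(t0) = ∂x0/∂θ_i`, giving one system of
dimension `N_x·(1+N_θ)`.  The initial condition is zero for rate parameters
and a unit entry on the matching state for initial-condition parameters —
this falls out of differentiating `x0(θ)` symbolically.  A central
finite-difference mode (relative step 1e-6) exists for black-box models; on
the linear-decay fixture it agrees with the forward equations to better than
1e-3 relative error.

Each sensitivity is scaled by `√w_i` (the same weights as the cost), stacked
over all records into an `N_D × N_θ` matrix, and summarized per parameter by
the root-mean-square score `msqr_i = sqrt(mean_j s̃_ij²)`.  Parameters whose
score falls below `ratio · max(msqr)` are classified practically
non-identifiable (non-influential) and excluded from the collinearity
analysis; the default ratio is 1e-4 (four orders of magnitude below the
maximum).  Borderline equality counts as influential — the inclusive choice
keeps more parameters under analysis.

## Collinearity index

The retained columns are normalized to unit Euclidean length (removing bias
from absolute sensitivity magnitudes).  For a subset `K`, with normalized
matrix `S̄_K`,

```
CI_K = 1 / min_{‖α‖=1} ‖S̄_K α‖ = 1 / sqrt(λ_min(S̄_Kᵀ S̄_K)).
```

`CI_K = 1` means mutually orthogonal sensitivity directions; large values
mean a change in one parameter is almost fully compensable by the others
(CI = 20 corresponds to 95% compensation, since `min‖S̄α‖ = 0.05`).  A
subset is identifiable iff `CI_K < CI*` (strict), with default `CI* = 20`.
Numerically, CI is computed from the smallest singular value of `S̄_K`
rather than an eigendecomposition of the Gram matrix — identical by
definition, better conditioned.  When `λ_min` falls below the floor 1e-12
the subset is flagged with an infinite CI (machine-precision rank
deficiency).  Key invariants, all under test: `CI ≥ 1`, singletons have
`CI = 1` exactly, CI is permutation-invariant, and CI never decreases when a
parameter is added to the subset.

## Largest identifiable subset

Maximizing the number of parameters subject to `CI < CI*` is a nonlinear
integer program over inclusion bitstrings.  It is solved in penalized form:

```
maximize Σ_k i_k − P1 − P2,
P1 = CI(S_i)/(2·CI*),                  P2 = 0 if CI < CI*, else (CI − CI*)².
```

`P1` equals 0.5 at the threshold — small enough never to change the optimal
size, but it makes the solution unique by favouring the lower-CI subset
among equal-size optima.  `P2` (penalty constants 1 and 2) softly enforces
the threshold.  The empty selection scores 0 by convention, and a
rank-deficient selection (infinite CI) scores −∞.

The search is a binary Variable Neighbourhood Search: the incumbent is the
longest prefix of the column-pivoted (rank-revealing) QR ordering of the
normalized matrix whose CI stays below the threshold (CI monotonicity makes
the scan stop at the first violation); shaking flips k random bits
(k = 1..k_max, default 4); local search is best-improvement single-bit
flips; an improving move resets k, otherwise k grows, and the search stops
after 20 neighbourhood sweeps without improvement (`stall`) or when the
evaluation budget (default 5000 per parameter; each evaluation is one
σ_min) is spent.  Results are deterministic given the seed and never worse
than the QR incumbent.  On planted matrices with up to ~10 columns the
search matches exhaustive 2^N enumeration (acceptance suite).

Threshold sweeps run one search per grid point, warm-starting each run with
the previous best subset — sound because a subset identifiable at a lower
threshold remains identifiable — which makes the reported size monotone
non-decreasing by construction.

## Enumerating all largest subsets and minimal collinear groups

Because any superset of a highly-collinear set is highly collinear,
admissible (CI < CI*) sets can be grown level-wise: start from admissible
pairs, extend each admissible set only by parameters of larger index
(canonical ordering generates every set exactly once), and evaluate a
candidate only if all its one-smaller subsets are admissible.  The last
non-empty level holds all maximum-size identifiable subsets.  The dual
search reports the *smallest* groups with `CI ≥ CI*` (sizes 2..6 by
default): a group is reported only if it contains no already-reported
smaller group, so every reported group is minimal — removing any member
drops the CI below the threshold.  Groups are labelled `G{size}({index})`
in discovery order.  Both enumerations are exponential in the worst case
and guarded (40 parameters for subsets, 25 for groups) with a `force`
override; the group threshold defaults to the same `CI*` as
identifiability.

A structural consequence, verified by test: from a minimal collinear group
of size K, at most K−1 members can appear in any largest identifiable
subset.

## Network export

Four boolean structural Jacobians are evaluated symbolically — `∂f/∂x`,
`∂g/∂x`, `∂f/∂u`, `∂f/∂θ` (plus `∂g/∂θ` for parameters appearing in
observation functions) — and thresholded at identically-zero after
simplification, so cancelling expressions such as `θx − θx` count as
structurally absent.  Each nonzero entry becomes a directed edge from
dependency to dependent (`x2 → x1` when `x2` appears in the equation of
`x1`).  Parameter nodes carry the identifiable flag from the subset
analysis; pairs whose CI reaches the threshold are joined by undirected
collinearity edges; minimal collinear groups appear as `GX(Y)` nodes with
undirected membership edges.  Node colours are left to the viewer: kind and
identifiability are exported as attributes, in GraphML (primary; exact
round-trip is tested) or SIF plus CSV attribute tables (secondary), both
readable by Cytoscape.  A numeric fallback probes the Jacobians at five
random points (threshold 1e-12) for models without usable symbolic
partials, and is flagged as heuristic.

## Synthetic fixtures: what they emulate and what they do not

Planted matrices exercise the collinearity machinery without ODEs.
Orthogonal columns come from a random rotation of the canonical basis; a
planted pair with target CI `c` uses inner product `ρ = 1 − 1/c²` (Gram
eigenvalues `1 ± ρ`); a planted group of size `g` appends a unit combination
of `g−1` columns plus a controlled orthogonal residual `d` with
`d² = 1 − (1 − 1/c²)²`, which hits the target CI exactly.  Setting the
target to infinity plants an exact linear dependence; notably, a rank-2
triplet has pairwise CIs far below the threshold while the triplet's CI is
infinite — the higher-order interplay the group search exists to find.

The kinetic fixtures follow the standard protocol for testing calibration
methods: simulate with nominal parameters, sample at equidistant time
points, add i.i.d. Gaussian noise, and weight records by `1/σ²`.  Default
noise is 5% (absolute sd 0.05 on observables of order 1, 20 samples per
observable).  The `cascade6` fixture plants one instance of each failure
mode in a three-state cascade: `k5` only moves an unobserved dead-end state
(non-influential for any θ, so the filter must always cut it), `k1` and
`k2` enter only through their sum (identical sensitivity columns, an exact
collinear pair), and `k3`, `k4`, `k6` are cleanly identifiable — `k6` is a
measurement background in the second observable, placed there because a
basal-production variant turned out to create a near-collinear
`{k3, k4, k6}` triplet under this sampling scheme, which would blur the
planted ground truth.  `product2` (`dx/dt = −p1 p2 x`) carries an exact
structural ridge: only the product is identifiable, which exercises the
regularization behaviour along a ridge.

The generators emulate dense, uniformly-weighted, additively-noisy
time-course data with known ground truth.  They do not emulate heteroscedastic
or missing measurements, model misspecification, correlated noise, or the
scale of real signalling/metabolic networks, so passing tests demonstrate
correctness of the algorithms under controlled conditions rather than
performance claims on any particular real dataset.

## Numerical and design choices

- Integrator tolerances rtol 1e-8 / atol 1e-10; sensitivity systems are
  integrated as one augmented ODE rather than by repeated finite
  differencing.
- CI floor: `λ_min < 1e-12` ⇒ infinite CI; identifiability comparisons are
  strict (`CI < CI*`).
- QR tie-break: LAPACK column pivoting takes the first column of maximal
  remaining norm, i.e. ascending parameter index on exact ties.
- Evaluation budgets, not wall-clock, bound all searches.  The bundled
  analyses use reduced budgets (calibration 1000-2500 evaluations, VNS
  2000-4000) chosen so the cascade problems are solved to the accuracy the
  tests assert while the whole suite stays lightweight; budgets are
  configuration, not tuning of the science.
- Weights: data files may carry `sigma` instead of `weight`; conversion is
  `w = 1/σ²`.  Noise-free fixture data gets unit weights.
- The workflow object runs sensitivities at the *estimated* parameter
  vector (matching the calibrate-then-analyse order); passing `theta`
  explicitly skips calibration and reproduces identical downstream results,
  which is also how stages are resumed from on-disk intermediates.

## Known limitations

- Enumeration and group partitioning are exponential; they are intended for
  models of moderate size (a few dozen parameters) and guarded accordingly.
  The VNS subset search and everything upstream scale much further.
- No event handling beyond piecewise-constant inputs; no DDEs/PDEs or
  stochastic simulation; no SBML import.
- The hybrid optimizer is a contract-equivalent member of the scatter-search
  family, not a bit-exact reproduction of any particular published solver.
- Collinearity analysis is local: it depends on the parameter vector at
  which sensitivities are evaluated, on the experimental designs, and on the
  weights.  Different stimuli or sampling schemes can change the verdict,
  which is precisely what makes the analysis useful for experiment design.
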