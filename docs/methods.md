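# Methods

## Model and objective

The data are a non-negative matrix X (n features × m samples), modeled as an
additive mixture of k non-negative components, X ≈ W Aᵀ. The solver minimizes

    F(W, A) = ‖X − W Aᵀ‖_F² + λ·J(W)
    subject to W ≥ 0, A ≥ 0, and 1ᵀaₗ = α for every column aₗ of A,

with the fit term carrying no ½ factor; every gradient, KKT expression and
closed-form update in the package is derived under this one convention, and
a finite-difference consistency test enforces that they stay mutually
coherent (this is why the ℓ1 soft threshold is λ/2, not λ).

The equality constraint confines each mixing column to the α-simplex
Δ_α = {a ≥ 0 : Σ aᵢ = α}. It is essential, not cosmetic: the supported
penalties are scale-dependent, and without the constraint the optimizer
would shrink W while inflating A without bound, making λ meaningless. W is
the regularized factor and A the scale-locked one, matching the expression
use case where sparsity is wanted in the gene loadings; the roles can be
interchanged by transposing the input.

Supported penalties J(W):

- **l1**: Σᵢₗ Wᵢₗ (entries are non-negative, so this is the entrywise ℓ1
  norm). Promotes exact zeros.
- **tikhonov**: ‖L W‖_F² for an n×n filter matrix L (identity, first or
  second difference operators, or user-supplied). Promotes smooth loadings.
- **related**: Σ_{(i,j)∈P} ‖wᵢ − wⱼ‖² = ‖W B‖_F², with B the signed
  incidence matrix of the pair set P (+1 at i, −1 at j per column). Pulls
  designated pairs of base vectors together. Pair indices are 0-based in
  the Python API; the CLI pairs file is 1-based to match the comp_1..comp_k
  column names.

Alternative losses (KL or other divergences) and simultaneous regularization
of both factors are out of scope.

## Block-coordinate descent with proximal safeguards

Coordinates are partitioned into blocks: each mixing column aₗ is a block;
for l1/tikhonov each component column wₗ is a block updated against the
rank-one residual R = X − Σ_{j≠l} wⱼaⱼᵀ; for the related penalty W is one
whole block (it decouples over feature rows) updated before the k mixing
columns. Sweep order is l = 1..k ascending, deterministic.

Each block subproblem is augmented with a proximal term τ‖·−previous‖².
Because all feasible sets are compact and the proximal term makes every
subproblem strictly convex, the iteration is monotone and its limit points
are critical points of the *original* F (the proximal term is not part of
F and vanishes at a fixed point). τ_a must be strictly positive — when a
base vector collapses to zero the mixing subproblem would otherwise be
flat, and the proximal term is what returns the previous coefficients
instead of an arbitrary simplex point. τ_w may be set to 0 by the user
whenever the component subproblem is strictly convex on its own (l1 with a
non-zero mixing column; tikhonov with λ LᵀL ≻ 0). Default
τ_a = τ_w = 1e-6·mean(X²): scale-aware, small enough to leave fixed points
of the unsafeguarded iteration essentially unchanged, large enough to keep
the restricted Gram systems numerically positive definite.

### Mixing-column update (exact simplex projection)

The subproblem in aₗ has the diagonal quadratic form (‖w‖² + τ_a)·I, so its
exact minimizer is the Euclidean projection onto Δ_α of
c = (Rᵀw + τ_a·a_prev)/(‖w‖² + τ_a). The projection sorts c descending and
scans once for the largest support size q with c_(q) − μ_q > 0, where
μ_q = (Σ_{i≤q} c_(i) − α)/q; the solution is h = max(c − μ_{q*}, 0). The
support provably consists of the q* largest coordinates (swapping a larger
excluded coordinate for a smaller included one would lower the objective),
and the early-exit form of the scan (stop at the first q with q = d or
μ_q ≥ c_(q+1)) selects the same q*; both rules are implemented and their
agreement is asserted by tests. Ties in the sort are broken by a stable
sort on index; strict convexity makes the projection value independent of
the tie order (checked by a permutation-equivariance property test).
Cost: one sort plus a linear pass per update.

### Component updates

- **l1**: per-coordinate KKT gives the soft threshold
  wᵢ = max(0, (Ra)ᵢ + τ_w·w_prev,ᵢ − λ/2)/(‖a‖² + τ_w), producing exact
  zeros (sparsity is measured as the fraction of exact zeros, eps = 0).
- **tikhonov**: an NNLS problem solved on its normal equations with
  G = (‖a‖² + τ_w)I + λ LᵀL and f = Ra + τ_w·w_prev, by the Bro–de Jong
  FNNLS active-set method — no stacked design or explicit Cholesky of the
  penalty is formed. With L = I the FNNLS path reproduces the closed-form
  shrinkage, which is a test.
- **related**: rows of W decouple; each feature row solves an NNLS with
  the shared k×k Gram G = AᵀA + λ BBᵀ + τ_w I computed once per call.

FNNLS tolerances are scale-aware (KKT entry test 1e-10·(1 + max|f|));
anti-cycling follows the Lawson–Hanson rule of removing the
boundary-hitting coordinate with the smallest step ratio, ties to the
lowest index; the inner-iteration budget is 30·d, and a non-positive-
definite restricted system raises immediately (it signals a missing
proximal term, not a recoverable condition).

### Residual bookkeeping

R is updated cumulatively (add wₗaₗᵀ back before updating block l, subtract
after) and refreshed from scratch every 10 sweeps and at the end, bounding
accumulated drift; a 50-sweep drift test verifies ‖R_cum − R_fresh‖_F ≤
1e-6·‖X‖_F.

## Stopping, convergence diagnostics

The iteration stops when the relative objective decrease
(F_prev − F)/F_prev falls below `tol` (default 1e-5) or the sweep budget
(default 500) is exhausted. Two first-order residuals are recorded every
sweep:

- kkt_w: max-norm of min(W, ∇_W F) elementwise, with
  ∇_W F = −2(X − WAᵀ)A + λ·∂J/∂W (for l1 the constant λ enters both the
  interior and boundary conditions);
- kkt_a: the worst simplex optimality gap over mixing columns — the
  largest excess of a partial derivative at a non-zero coordinate over the
  smallest partial derivative of that column.

Both vanish exactly at critical points. The trace's `converged` flag is
stricter than the objective criterion alone: it additionally requires both
residuals to have dropped below 1e-3 of their initial values (with an
absolute floor at rounding noise); the plain objective criterion is
reported separately as `objective_converged`, so either convention is
recoverable from the trace.

## Sparsity-targeted weight selection

The λ needed for a given zero fraction varies between data sets, so it is
found by search: starting from 1e-6·mean(X), λ is doubled until the
converged fit reaches the target zero fraction, then at most 25 bisection
steps refine it, every evaluation refitting from the *same* seeded
initialization so that achieved sparsity is a reproducible, near-monotone
function of λ. The best λ seen (achieved sparsity closest to the target)
and its fit are returned; the search stops early once the gap is below a
quarter of the ±0.02 acceptance band.

## Initialization

W entries are Uniform(0,1) scaled by mean(X)/k; A columns are Uniform(0,1)
rescaled to sum exactly to α. All randomness flows from a single integer
seed through one generator. The initial scale of W is immaterial: the
first component-block update is an exact minimization given A, so the
iteration forgets it after one sweep.

## Synthetic data

The generator plants ground truth the method assumes: W_true = |N(0,1)|
entries with an exact count round(s·n·k) of uniformly placed zeros
(redrawn if a column would be all zero), A_true columns flat Dirichlet over
the m samples scaled by α, and X = max(0, W_true·A_trueᵀ + N(0, σ)). The
truncated Gaussian respects non-negativity with a single dispersion
parameter and emulates non-log microarray intensities only at the level of
non-negativity and additive structure — no probe-level artifacts, batch
effects or heavy-tailed platform noise. Passing recovery tests therefore
demonstrates correctness of the optimization and identifiability under the
planted model, not robustness to real-platform noise. Default study
conditions used throughout the tests: n = 60, m = 40, k = 4, α = 1,
planted sparsity 0.5, noise sd 0.05.

Recovered components are aligned to the truth by Hungarian assignment on
the k×k cosine-similarity matrix (NMF is identifiable only up to component
permutation; zero columns get similarity 0).

A known limitation, measured on the noiseless planted instance: at the λ
that yields 50% zeros, the implied per-entry threshold (~0.3 in W units)
exceeds roughly a tenth of the planted |N(0,1)| magnitudes, so those small
true entries are unavoidably zeroed and the zero-pattern F1 plateaus near
0.89 even though the matched cosines reach 0.99 and the KKT residuals
certify criticality. Support recovery at a fixed sparsity level is limited
by the soft-threshold bias of ℓ1, not by the optimizer.

## Numerical choices and degenerate inputs

- Exact scale: mixing columns sum to α up to ~1e-12·α·d per projection;
  the model container rejects drift beyond 1e-9·α.
- A zero base vector is tolerated (proximal safeguard); a zero mixing
  column with τ_w = 0 is an error for the l1 update (subproblem not
  strictly convex).
- k > min(n, m) is allowed with a warning (overcomplete).
- Monotonicity is asserted at 1e-10 relative tolerance; block updates are
  exact minimizations, so violations indicate bugs, not roundoff.
- Problem sizes in the test suite (n ≤ 100, m ≤ 60, k ≤ 6) are chosen so
  the full suite and the acceptance computation run in seconds on one
  core while exercising every code path at realistic conditioning.
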