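# Methods

## Model

A partially observed matrix **F** (m row entities × n column entities; in
the motivating application, patients × diagnostic criteria) is completed
jointly with a bilinear side-information model. Row features **X**
(d₁ × m) and column features **Y** (d₂ × n) are each augmented with an
all-ones row so that the interaction block **H**, the linear effects
**u**, **v** and the intercept γ fold into one matrix
**G** = [[H, u], [vᵀ, γ]] of size (d₁+1) × (d₂+1), and every entry is
predicted as x̄ᵀ**G**ȳ. The estimate solves

    min_{G,E}  ½‖XᵀGY − E‖²_F + λ_E‖E‖_* + λ_G‖G‖₁
    s.t.       R_Ω(E) = R_Ω(F),

with Ω the observed set. The nuclear norm encodes the low-rank prior on the
completed matrix; the ℓ₁ norm selects a sparse set of feature interactions.
The program is convex; G itself is deliberately not rank-constrained. As
λ_G → ∞, G vanishes and the program reduces to nuclear-norm completion
without side information.

Assumptions worth keeping in mind: entries are real-valued (binary
endorsements are treated as real scores; no link function), noise is
homoscedastic, and the observed set is missing (completely) at random —
the synthetic benchmark removes entries uniformly.

## Algorithm

With slack **C** = **E** − **X**ᵀ**G****Y**, the augmented Lagrangian (penalty β)
is optimized in the block order C → G → E followed by dual ascent on both
multipliers. C has a closed form. The G block is a LASSO in g = vec(G)
whose design **A** = Yᵀ ⊗ Xᵀ has nm rows and is never materialized: each
iteration draws s rows uniformly without replacement (refreshed every
iteration from the seeded generator), forms the s-row block explicitly,
linearizes the sampled quadratic around gᵏ and applies one
soft-thresholding step with threshold λ_G/(τ_k β). The E block takes one
singular-value-thresholding (SVT) step with threshold λ_E/(2βτ′_k). The
deterministic variant (`fit_ladmm`) is the same iteration with the full
gradient computed in matrix form, vec(X(XᵀGY − B)Yᵀ). When the stochastic
solver is asked for s ≥ nm it still builds the explicit row block, so the
two solvers provide genuinely independent routes that must agree — a
property the test suite checks to 1e−8.

Column-major vectorisation is used throughout: vec stacks columns, entry
(i, j) of F has linear index r = j·m + i, and row r of A is
kron(Y[:, j], X[:, i]).

### Proximal parameters

The linearization is valid when τ_k majorizes the curvature of the sampled
quadratic. The default policy (`tau_policy="linearized"`) uses
τ_k = 0.99·σmax(Aᵏ)² and τ′_k = 0.99 (each E-side quadratic has unit
curvature). On the stochastic path τ_k additionally grows like √(k+1):
the sampled gradient carries the multiplier noise M₂/β into every step, and
with a constant proximal parameter the G iterate random-walks around the
solution instead of settling; √k growth is the standard schedule under
which stochastic ADMM attains its O(1/√k) rate.
An alternative policy (`tau_policy="paper"`) sets τ_k just below ‖A‖ and
τ′_k just below ‖R_Ω(F)‖_F — the rule sometimes quoted for this family —
with a divergence guard that doubles the parameter whenever a subproblem
objective increases; it is kept for comparison, not as the default, because
‖A‖ under-damps the G step by a factor of ‖A‖ and ‖R_Ω(F)‖_F over-damps
the E step by orders of magnitude on realistic scales.

### Sampling, gradient scaling, parallelism

The block size defaults to s = max(1, round(√(ab/100))) — a handful of rows
even for very large problems. The sampled gradient f₁ = (Aᵏ)ᵀ(Aᵏg − b̃) is
the plain sum over sampled rows; an unbiased variant rescaled by nm/s is
available (`rescale_gradient=True`) but off by default since τ_k absorbs
the scale. Gradient shards may be computed in parallel (`n_jobs`); shards
partition the sampled index set, never change it, and their sum equals the
sequential value up to floating-point reordering.

### Initialization and stopping

M₁⁰ and M₂⁰ are standard Gaussian (seeded). E⁰ is the output of a few
(default 10) iterations of the classic SVT completion solver. G⁰ is the SVT
(threshold λ_G) of the ridge least-squares solution of XᵀGY ≈ F restricted
to the observed entries, computed by LSQR on the implicit masked Kronecker
operator (damp 10⁻³, 30 iterations); `g_init="zero"` is the documented
fallback. On well-conditioned problems this initialization already explains
most of the signal — the ADMM iterations then enforce the constraint
structure and the two penalties around it.

Iterations stop when the observed-entry residual ‖R_Ω(E−F)‖_F and the
coupling residual ‖E − XᵀGY − C‖_F (both relative to ‖R_Ω(F)‖_F) and the
relative change in E all fall below `tol` (default 10⁻⁴), or at `max_iter`
(default 500); hitting the cap returns `converged=False` rather than
raising.

### SVT at scale

The SVT operator uses a full LAPACK SVD when the smaller dimension is at
most 256. Above that it uses a randomized truncated SVD whose rank starts
at a hint carried over from the previous iteration and doubles until the
smallest retained singular value falls below the threshold, falling back to
a full SVD once the rank passes a quarter of the spectrum (at that point
LAPACK is cheaper and exact).

## Synthetic benchmark

The generator draws each feature row of X and Y from a distribution picked
uniformly among Gaussian(0,1), Poisson(1) and Gamma(1,1) (the three
families named for the benchmark; scale parameters are our defaults, chosen
unit-scale so the interaction signal dominates, and configurable). The
ground-truth G places round(density·d₁d₂) nonzeros uniformly at random with
N(0,100) values and is redrawn (bounded retries) until its numerical rank
is at least min(d₁,d₂) − 1; the support density is not specified by the
benchmark and defaults to 0.3. F = XᵀGY + N with N(0,1) noise, built from
the *unaugmented* sides (consistent with the benchmark's reported
recovered rank d₁); exactly round(q·mn/100) entries are then removed
uniformly at random.

Settings I/II (200×200) use 15×200 and 20×200 features, setting II adding
one linearly dependent row to each side; setting III (1000×1000) uses
20×1000 and 25×1000 with five dependent rows each. Setting IV (the
large-matrix timing/accuracy benchmark) has unstated side dimensions in its
source; we default to setting III's sizes with full-row-rank features.

What the generator does *not* emulate: linkage disequilibrium or allele-
frequency structure in genotypes, family relatedness, binary criterion
endorsements, and informative missingness. Passing benchmarks here
demonstrates correct optimization and recovery under the stated sampling
model, not robustness to those real-data features.

## Evaluation protocol

Accuracy is the relative mean squared error on missing entries,
‖R_Ω̄(XᵀGY − F)‖²/‖R_Ω̄(F)‖², scale-invariant by construction. Tuning holds
out 30% of the *given* entries as a validation set, fits every point of a
powers-of-ten grid 10⁻³…10⁴ over (λ_E, λ_G) — full cross product by
default, a tied λ_E = λ_G mode to cut cost — averages validation RMSE over
3 splits, and keeps the argmin (grid order breaks ties). The experiment
harness repeats generate→tune→fit→score over q sweeps and seeds and
records per-cell RMSE, recovered ranks (of the H block and of E, counting
singular values above 10⁻⁶ of the largest), wall time and the chosen λs;
solver failures are recorded per cell.

## Problem sizes used in the shipped tests

To keep the default test run within a desktop budget, the large-matrix
reproduction uses the full 1000×1000 generation with a reduced tuning
protocol (tied 3-point grid, one validation split, 8-iteration tuning fits)
and a fixed 25-iteration budget per final fit over 3 seeds; the 200×200
rank-recovery check uses 5 seeds, q ∈ {10, 50}, a tied 2-point grid and
200-iteration fits. `scripts/acceptance.py` runs the full q = 10…90 sweep
at 200×200 with a tied 8-point grid, two validation splits per point and
300-iteration final fits. Small-instance oracle tests (Kronecker identity,
proximal steps, solver equivalence) are exact and fast.

## Known limitations

* With the default tiny sampling block, the stochastic solver's G step
  injects multiplier noise (M₂/β, large when β = 0.01) into each sampled
  target; the √k proximal growth damps it, but on heavily masked large
  problems the last iterate can plateau well above the deterministic
  solver's error. The deterministic `fit_ladmm` is preferable whenever the
  full gradient is affordable.
* Predicted criteria are returned as raw real scores; a thresholding
  utility is provided but no probability calibration.
* The observed-entry constraint is enforced via the penalty/multiplier
  pair, so R_Ω(E) matches R_Ω(F) only up to the convergence tolerance; the
  `impute` command overwrites observed cells with their measured values.
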