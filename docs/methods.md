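# Methods

## Model

`hubernet` infers the topology of a gene regulatory network (GRN) of `p`
genes from `m` time-course expression datasets measured under different
conditions.  Each dataset `k` with `n_k + 1` timepoints is modelled as a
first-order vector autoregression

    x̃_{t+1}(k) = A(k) x̃_t(k) + e_t(k),

where `A(k)` is the condition-specific regulatory matrix and `e_t(k)` is
measurement/process error.  Entry `(i, j)` of `A(k)` is the strength with
which gene `j` drives gene `i`; all `A(k)` share a single zero pattern —
the network topology — but not their values, because regulatory strength
varies with conditions.  Self-regulation (the diagonal) is estimated like
any other coefficient but excluded from topology scoring.

Rows of the `A(k)` decouple, so inference runs per target gene `i`.  The
`m` copies `a_il(1), …, a_il(m)` of edge `l → i` form one coefficient
group `b_il`, and the stacked problem over all datasets is

    J(b) = Σ_j ω_j H_δ(y_j − x_jᵀ b) + λ Σ_l ‖b_l‖₂,

with observation weights `ω_j = w_k = n_k / Σ n_k` for rows from dataset
`k`, and `H_δ` the Huber loss

    H_δ(θ) = θ²            for |θ| ≤ δ,
    H_δ(θ) = 2δ|θ| − δ²    otherwise.

The group-L2 penalty removes or keeps an edge jointly in every dataset;
the Huber loss bounds the influence of gross errors (its derivative is
clipped at ±2δ).  The plain group LASSO is the δ → ∞ limit and is
implemented exactly that way (`loss="squared"`).

## Solver

`J` is convex but nonsmooth (the penalty at group zeros, the loss at ±δ).
It is minimised by cyclic block-coordinate descent on a quadratic
majorizer: at iterate `b'`, the smooth part `f` is replaced by

    Q(b | b') = f(b') + ∇f(b')ᵀ(b − b') + 2γ‖b − b'‖² + λΣ‖b_l‖,

which dominates `J` whenever `2γ` is at least the curvature of `f`
(guaranteed because `H_δ'` is 2-Lipschitz, so the Hessian of `f` is
bounded by twice the weighted Gram matrix).  Restricted to one group, `Q`
has the closed-form minimiser

    v   = Σ_j ω_j H_δ'(y_j − x_jᵀ b) x_{j,l} + 4γ b_l
    b_l ← (1/(4γ)) (1 − λ/‖v‖₂)₊ v,

a group soft-threshold producing exact zeros.  Each full cycle therefore
decreases `J` monotonically, and the iterates converge to the global
minimum; both properties are asserted by the test suite (per-cycle descent
to 1e−12; objective agreement with an independent accelerated
proximal-gradient solver to 1e−5 relative; first-order optimality residual
below 1e−4).

Two implementation choices matter for practice:

- **Per-block curvature.**  Because only one group moves per update, `γ`
  needs to dominate the curvature of `f` along that group only, and each
  group's bound (top eigenvalue of its own weighted Gram block) is used by
  default.  The per-dataset columns of one group have disjoint row support,
  so these blocks are diagonal and far smaller than the global bound when
  genes are correlated — which lagged expression trajectories always are.
  With the single global bound (`gamma_mode="global"`, retained as an
  option and used in the majorization tests) the Huber solves can need
  ~10× more iterations and routinely hit the iteration cap on realistic
  data.
- **Compiled kernels.**  The cycle loop is JIT-compiled (numba) with the
  design held transposed for contiguous access; stability selection solves
  3 000 penalised regressions per run and is impractical otherwise.

Convergence is declared when the largest coefficient change over a full
cycle falls below `tol` (default 1e−6; `max_iter` 10 000).  Ties are
deterministic: `‖v‖ = 0` maps to an exactly zero block.

## Penalty path

`λ_max = max_l ‖Σ_j ω_j H_δ'(y_j) x_{j,l}‖₂` is the smallest penalty whose
solution is the empty model (evaluated at `b = 0`).  A solution path uses
a log-spaced grid from `λ_max` down to `0.01·λ_max` (20 values by
default), warm-starting each solve from the previous one.

## Choice of the Huber transition point δ

δ is set per target gene from the data, once, before any resampling:

1. Fit the **pooled** autoregression (a single coefficient vector shared
   by all datasets — `p` parameters) by weighted least absolute deviations
   (LAD, solved exactly as a linear program; a ridge-guarded IRLS handles
   rank-deficient designs).
2. σ̂ = (mean |r − median r|) / 0.6745 over the pooled residuals.
3. δ = max(1.345 σ̂, 1).

1.345σ is the classical tuning giving 95% efficiency at the Gaussian; the
floor of 1 guards against an overfit LAD.  The pooled fit is deliberately
parsimonious: its residuals contain both noise and the across-dataset
spread of regulatory strengths, which is the scale of residuals the
grouped solver actually sees while supports are still being resolved.  The
mean (rather than median) deviation responds to the contaminated tail.
Both choices are deliberate: with a full per-dataset LAD fit and a median
deviation, δ collapses to the small-noise scale; the Huber gradient is
then saturated at almost every observation during support discovery, edge
selection degenerates to sign information, and the robust loss performs
*worse* than the squared loss — the opposite of its purpose.  The
classical median scale remains available (`estimate_delta(..., scale="median")`)
and a fixed δ can be supplied (`--delta`).  δ is held fixed across the
penalty grid and all bootstrap replicates of its target so robustness
tuning is not conflated with resampling noise.

## Stability selection

Edges are scored by selection frequency under data perturbation:

1. Fix the penalty set Λ from the original family: a 20-point log grid
   from the largest per-target `λ_max` down to 1% of it.  Fixing Λ before
   resampling keeps "selected at λ" comparable across replicates.
2. For each of N = 30 replicates, resample every dataset by a **moving
   block bootstrap on transitions**: the `n` consecutive
   (predecessor, successor) column pairs form `n − l + 1` overlapping
   blocks of length `l`; `⌊n/l⌋` blocks are drawn with replacement and
   concatenated.  Resampling whole transition pairs preserves the
   regression structure exactly (no fabricated transitions at block
   seams) and short-range temporal dependence within blocks.
3. Solve all `p` target problems along Λ for each replicate; edge
   `(i, j)` is selected at λ iff group `j` of target `i` is nonzero
   (groups are exactly zero or jointly free).
4. Π_λ(i,j) = (#replicates selecting the edge at λ)/N, and the final
   score is Π(i,j) = max over the **sparse stretch** of Λ.

The sparse-stretch restriction: frequencies accumulate only while a
target's solution holds at most ⌈p/2⌉ nonzero groups (configurable).
Without it the small-λ tail of the grid selects every group in every
replicate — for the Huber loss this is structural, because `λ_max` is
computed at saturated gradients and scales with 2δ while residual
gradients scale with the data — and every score saturates at 1, carrying
no ranking information.  Restricting the regularisation region to sparse
models is the standard device of stability selection; it is the package's
resolution of a protocol detail the grouped-robust literature leaves
open.  Non-converged solves are counted as non-selecting and reported as
a warning count on the result.

## Evaluation

Scoring is unsigned and ignores self-loops: positives are the nonzero
off-diagonal entries of the gold standard, candidates are all off-diagonal
pairs.  ROC and precision–recall curves sweep the distinct score values
(stability scores take at most N+1 values, so ties are grouped — the
AUROC equals the Mann–Whitney statistic with half-credit for ties, which
the tests verify by brute force).  Areas are trapezoidal; the artificial
recall-0 endpoint of the PR curve carries the precision of the
highest-score group rather than an interpolated 1.

## Synthetic benchmark

The generator reproduces a 5-gene study design: a fixed signed template
(13 regulatory interactions, 8 off-diagonal), `m` condition matrices
`A(k)` with the template's exact sign pattern, and noisy trajectories.

- **Magnitudes**: nonzero entries uniform on [0.2, 1.0] with the
  template's sign, then the matrix is rescaled so its spectral radius
  equals a target drawn uniformly on **[0.7, 0.95]**.  Rescaling
  guarantees stability without rejection sampling.  The radius range keeps
  the dynamics persistent: innovations propagate over several transitions,
  so the lagged predictors carry regulatory signal well above the
  small-noise floor throughout the window.  With radii much below ~0.7 the
  trajectory information decays into the noise floor within the 16-point
  window and no estimator recovers the topology reliably.
- **First timepoints**: i.i.d. uniform on [1, 10] (positive, O(1)-scale
  levels).  Because noise accumulates through the recursion, the
  stationary signal scale is set by the dynamics, not by the initial
  level.
- **Noise**: each error entry is N(0, 1) with probability 0.8 and
  N(0, 10²) with probability 0.2 — routine measurement error plus a 20%
  rate of gross outliers (mixture variance 20.8, verified by a moment
  test).  Noise enters the recursion, so an outlier also perturbs the
  subsequent predictor column: contamination corrupts the design as well
  as the response, which is the harder, realistic case.
- **Seeding**: one master seed; per-dataset substreams are spawned so
  increasing `m` leaves earlier datasets unchanged.

Three study conditions are benchmarked, matching dataset counts, lengths
and block lengths of (m=8, n_k=15, l=10), (m=4, n_k=15, l=10),
(m=4, n_k=8, l=5), each with N = 30 bootstrap replicates, both losses,
AUROC/AUPR medians over 10 independent simulation seeds
(`hubernet.pipeline.run_simulation_benchmark`).

What the generator does *not* emulate: mRNA degradation kinetics and the
continuous-time dynamics behind the discrete map; non-Gaussian or
serially correlated noise beyond the two-component mixture; unequal or
missing timepoints; gene sets differing across datasets.  Passing the
benchmark shows the estimator recovers linear first-order dynamics with
heavy-tailed errors at realistic sample sizes — not that real microarray
series satisfy those assumptions.

## Numerical and degenerate-input conventions

- All-zero response: `λ_max = 0` and the path is the zero solution.
- All-zero design: curvature undefined; raised as an error.
- All-zero block: its curvature falls back to the global bound (the
  update is zero regardless).
- Missing values are rejected at parse time with the offending cell
  named; datasets must share one gene order.
- Expression tables round-trip bit-exactly (17-significant-digit writes,
  round-trip float parsing).
- Selection calls a group nonzero when its norm exceeds 10× the solver
  tolerance (soft-thresholding makes true zeros exact, so this is slack).

## Known limitations

- The model is linear and first-order; feedback through unmeasured
  species, saturation and measurement nonlinearity are outside it.
- With a single trajectory per dataset and no noise the autoregression is
  not identifiable (the trajectory collapses onto the dominant eigenmode);
  the clean noise component is the excitation that makes topology
  recoverable.  Very smooth, low-noise real series will show the same
  degeneracy.
- Stability scores are comparative, not calibrated probabilities; no
  error-rate bound is attached to a threshold choice.
- The bootstrap shortens each dataset to `⌊n/l⌋·l` transitions; very
  short series (n < 2l) lose up to half their data per replicate.
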