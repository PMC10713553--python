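# Methods

`dfgl` implements estimation and inference for a logistic regression
model over `G` independent subpopulations that share a common covariate
space but may differ in covariate effects. This note records the model,
the algorithmic and numerical choices, what the synthetic generators
emulate, and known limitations.

## Model

Within group `g`, responses are Bernoulli with logistic link,

    y_i^(g) | x_i^(g)  ~  Bernoulli( sigma( x_i^(g)' beta^(g) ) ),

with group-specific coefficient vectors `beta^(g)` collected into the
`p x G` matrix `B`. There is **no intercept**: designs are centered
within each group and each column is rescaled to Euclidean norm
`sqrt(n_g)`, so coefficients describe log-odds relative to group-wise
covariate means. Two structural assumptions drive the method:

* **row sparsity** — only a few covariates are active in any group
  (the support `S = {j : ||B_(j)||_2 != 0}` is small);
* **fusion sparsity** — active covariates mostly have the *same* effect
  across groups (few pairs `(j, g, g')` with `B_jg != B_jg'`).

The two scientific questions are, per covariate `j`:
*significance* (`B_j1 = ... = B_jG = 0`?, chi-squared with `G` df) and
*homogeneity* (`B_j1 = ... = B_jG`?, chi-squared with `G-1` df).

## Penalized estimation

The fused group Lasso objective is

    L_n(B) + lambda1 * sum_j w_j ||B_(j)||_2
           + lambda2 * sum_j sum_{g<g'} v_{j,gg'} |B_jg - B_jg'|,

where `L_n` is the pooled average logistic loss. A unit-weight fit
serves as pilot; adaptive weights `w_j = 1/||pilot row||_2`,
`v = 1/|pilot difference|` (capped at 1e8 when a denominator is zero,
which effectively excludes the variable or fuses the pair) then sharpen
selection and fusion in a second, weighted fit.

### Algorithm

Outer loop: proximal gradient with the fixed step `1/eta`, where `eta`
is a Lipschitz bound of the gradient of `L_n`. Two valid bounds are
offered: the Frobenius bound `sum_g ||X^(g)||_F^2 / (4n)` (equal to
`p/4` on standardized data; the default of `fit_fgl`) and the spectral
bound `max_g lambda_max(X^(g)'X^(g)) / (4n)`, which on wide designs is
one to two orders of magnitude smaller and makes the iteration converge
within the default budget — the two-stage driver and the Monte-Carlo
runner use it (`SolverConfig(step_rule="spectral")`). With the
Frobenius step and `(m, p) = (200, 80)`, 200 iterations stop visibly
short of the optimum; with the spectral step the same budget converges
(relative-change exit around iteration 150). Inner loop: the proximal
subproblem is solved by ADMM with surrogates `A` (row sparsity, updated
by row-wise group soft-thresholding) and `F` (pairwise differences,
updated by entrywise soft-thresholding of `B H`, where `H` is the
signed pair-difference matrix), plus dual ascent on `U`, `W`. The
`G x G` linear system of the B-update, `rho H H' + (eta + rho) I`, is
symmetric positive definite and factored once per fit.

Defaults: `rho = 1`, `S = 50` inner iterations, at most `T = 200` outer
iterations. An early exit triggers when the relative Frobenius change
of the outer iterate falls below `1e-5`; set `outer_tol = 0` to disable
it. Cross-validation paths are warm-started along the penalty grid and
the final fit is initialized at the pilot. Callers who need very tight
optima (for example the oracle-equivalence tests) pass a larger `T` and
a smaller tolerance explicitly.

The returned solution is the ADMM surrogate `A`, so row sparsity is
exact. Within-row entries closer than `1e-8` are snapped to their
cluster mean, making the fusion set `Omega_hat` a statement about exact
equalities; in practice the A-iterate already carries exact ties when
the fusion weights are active. The numba-compiled inner kernel falls
back to pure numpy when no JIT is available, with identical arithmetic.

### Tuning

The path anchor is the theory rate `lambda1* = sqrt(16 G (log p +
log G) / n)` with the companion `lambda2 = G^(-3/2) lambda1`. Because
the constant 16 is conservative, the default grid log-spaces `lambda1`
over `(0.002, 1.0) * lambda1*` (wide enough that cross-validation does
not pin its choice to the grid boundary); the default grid is the 10 x 10 product
of that path with `lambda2/lambda1` ratios spanning a decade either
side of `G^(-3/2)` (a `paired` mode fixes the ratio at `G^(-3/2)` for
cheaper scans). Searching `lambda2` independently matters: on the
balanced design the best fusion ratio is about three times `G^(-3/2)`,
and with it the homogeneous strong rows pool across all groups, which
sharply improves both estimation and downstream test behavior. The
Monte-Carlo drivers here use scaled grids (6x6 product, or short paired
paths where fusion is immaterial). Selection is 5-fold cross-validation, folds drawn
within each group so every fold inherits the group proportions; the
criterion is mean held-out binomial deviance; exact ties break toward
the larger penalty. Two selection rules are available: the deviance
minimizer (default, best for prediction) and the one-standard-error
rule (`rule="1se"`), which picks the largest penalty within one SE of
the minimum — preferable when support/fusion recovery is the goal,
because the deviance curve is flat near its minimum and the minimizer
drifts into overfitting. A fold whose training part is single-class in some
group triggers a redraw with a shifted seed. Both stages re-tune by
default; `CVSpec(reuse_lambdas=True)` reuses the pilot's pair.

## Debiasing

Per group, the observed information `Sigma_hat^(g)` is evaluated at the
fitted coefficients. The decorrelation matrix `M_hat^(g)` solves, row
by row,

    min 1/2 m' Sigma m   s.t.  || Sigma m - e_j ||_max <= mu_g,

with `mu_g = c sqrt(log p / n_g)` and `c = 0.7` by default (`c` is a
single scalar shared across groups, exposed as a knob). The QP is
solved through its equivalent lasso-type dual
`min 1/2 m' Sigma m - m_j + mu ||m||_1` by cyclic coordinate descent;
for PSD `Sigma` the KKT systems coincide, so the converged point is the
QP optimum and satisfies the constraint automatically. All `p` rows are
solved in one vectorized slab (they share `Sigma`); rows are independent
problems, so results do not depend on execution order. When a row's
constraint cannot be met — typical when `p > n_g` makes `Sigma`
singular — its `mu` is inflated by 1.5, at most 20 times, and the level
actually used is recorded. Note the QP genuinely shrinks: for
`Sigma = I` the optimum is `(1 - mu) e_j`, not `e_j`.

The one-step correction is `b^(g) = beta_hat^(g) - M_hat^(g) s^(g)`
with `s^(g)` the average score at the fit, and the variance estimate is
`V_hat^(g) = M_hat Sigma_hat M_hat'`. Per-feature variances below
`1e-12` raise rather than clamp, to avoid silently inflated statistics.

## Testing

For covariate `j`, with `V_(j) = diag(V^(g)_jj / n_g)`:

* significance: `b_(j)' V_(j)^{-1} b_(j)` vs chi-squared(G). A
  specified common value `c` is tested by shifting `b_(j)` by `c`.
* homogeneity: `b_(j)' D' (D V_(j) D')^{-1} D b_(j)` vs
  chi-squared(G-1), with `D` the first-difference contrast. The
  statistic is computed as a quadratic form via a linear solve (not an
  explicit inverse square root) — mathematically identical and
  numerically safer; any full-rank recombination of `D` gives the same
  value.

Multiple testing across covariates uses the Holm step-down adjustment
(FWER control). Equal p-values share the larger adjusted value.

The chi-squared approximation is accurate at moderate sizes (empirical
type-I error pooled over null features lands at the nominal 5% for
`G = 3`, `p = 10`, `n_g = 500`), with a mildly light extreme tail —
the score is a weighted sum of bounded (Bernoulli) terms whose fourth
cumulant sits below the Gaussian's. Per-feature rejection-rate
estimates at a few hundred replicates are noisy (binomial), so the
calibration tests pool the estimate over all null features.

## Synthetic data

Covariates are i.i.d. `N(0, Sigma_x)` with either AR(1) correlation
(`0.5^|i-j|`) or a block-diagonal matrix of 4x4 Toeplitz(0.5) blocks;
responses follow the logistic model exactly. Two designs are built in:
a balanced one (`G = 7` equal groups; 12 structured coefficient rows
mixing sign-flipped 0.6/0.4 patterns, constant rows 0.4/-0.4/1.5/2.5,
and nulls) and an imbalanced one (`G = 3`, sizes 90/70/40, `p = 300`,
six active rows at fixed indices, four heterogeneous). Replicate `r`
seeds its generator as `base_seed XOR r`, so every table cell is a pure
function of the scenario and the base seed and replicates can be
recomputed independently or in parallel. Failed replicates (e.g. a
degenerate CV fold) are redrawn with a shifted seed and counted; more
than 5% failures aborts the experiment.

What the generators do **not** emulate: real expression data are
non-Gaussian, heteroscedastic, and correlated between groups;
group labels can be noisy; effects need not be exactly equal under
"homogeneity". Passing tests therefore certify the method's behavior
under its own model, not robustness to these violations.

The Monte-Carlo drivers in the test-suite and the acceptance script run
scaled-down (20-300 replicates, paired 4-8 point grids); the balanced
design is also exercised at a reduced `(m, p) = (100, 16)` where the
signal ordering, not the dimension, is the point. Full-size runs
(`M = 100`, 10x10 grid, `(m, p) = (200, 80)` or `(300, 120)`) are
available through `dfgl simulate` for overnight use.

## Screening and binarization (application preprocessing)

For drug-response panels, IC50 values below 0.5 are coded "sensitive"
(1), others "resistant" (0) — the threshold is strict `<`. The
dimension screen keeps the `K1 = 3000` columns with the largest sample
variances, then fits per column a logistic regression of the response
on that column plus an intercept and `G - 1` cancer-type dummies and
keeps the `K2 = 300` columns with the smallest Wald p-values. Perfect
separation in a marginal fit records a conservative p-value of 1 with a
warning rather than aborting. Ties in either ranking break toward the
lowest column index, so the screen is deterministic.

## Known limitations

* Only the logistic loss is implemented (the architecture would admit
  other GLM losses); no FISTA acceleration, no adaptive `rho`.
* The decorrelation QPs become expensive for `p` in the high hundreds;
  rows are independent, so parallelization is straightforward but not
  built in.
* No missing-response handling and no quantitative-response mode.
* FWER control only; no FDR procedures or simultaneous confidence
  bands.
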