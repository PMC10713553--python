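# dfgl — debiased fused group Lasso for grouped logistic regression

`dfgl` asks, for each covariate in a high-dimensional logistic
regression over `G` heterogeneous subpopulations: *does it matter at
all?* and *does it act the same way in every subpopulation?* The
motivating application is pharmacogenomics — testing whether a gene's
effect on binary drug sensitivity (IC50 below threshold) is shared
across cancer types — but the machinery is generic: any grouped binary
outcome with shared covariates.

## The method

Within group `g`, `y | x ~ Bernoulli(sigma(x' beta^(g)))`, with the
`p x G` coefficient matrix `B = [beta^(1) ... beta^(G)]` assumed
row-sparse (few active covariates) and fusion-sparse (active covariates
mostly share their effect across groups). Estimation minimizes

    L_n(B) + lambda1 * sum_j w_j ||B_(j)||_2
           + lambda2 * sum_j sum_{g<g'} v_{j,gg'} |B_jg - B_jg'|

by a proximal-gradient outer loop with an ADMM inner solver, in two
stages (unit weights, then adaptive weights from the pilot), with
penalties tuned by group-stratified 5-fold cross-validation.

Because penalized estimates are biased, inference uses a one-step
correction: per group, a decorrelation matrix `M_hat^(g)` —
an approximate inverse of the observed information obtained row-wise
from the quadratic program
`min ½ m' Sigma m  s.t.  ||Sigma m − e_j||_max <= mu_g` —
yields debiased coefficients `b^(g) = beta_hat^(g) − M_hat^(g) s^(g)`
and variances `V_hat^(g) = M_hat Sigma_hat M_hat'`. Two chi-squared
tests follow for each covariate `j`:

* **significance** (`beta_j = 0` in every group): statistic
  `b_(j)' V_(j)^{-1} b_(j)`, df `G`;
* **homogeneity** (`beta_j` equal across groups): statistic
  `b_(j)' D'(D V_(j) D')^{-1} D b_(j)` with first-difference contrasts
  `D`, df `G − 1`.

Holm's step-down adjustment controls the familywise error rate across
covariates. See `docs/methods.md` for assumptions, defaults and
numerical details.

## Worked example

```python
import numpy as np
import dfgl

# three groups, 120 samples each, 30 covariates; covariate 0 acts
# everywhere (+1.2), covariate 1 flips sign in group 3
truth = np.zeros((30, 3))
truth[0] = 1.2
truth[1] = (0.8, 0.8, -0.8)
spec = dfgl.ScenarioSpec(
    G=3, p=30, group_sizes=(120, 120, 120), covariance_kind="ar1",
    true_B=dfgl.CoefficientMatrix(truth), reps=1, base_seed=7,
)
data = dfgl.simulate_dataset(spec, rep=0)

pilot, fit = dfgl.fit_dfgl_two_stage(
    data, cv=dfgl.CVSpec(n_points=8, mode="paired", seed=0)
)
print(sorted(fit.S_hat))          # selected covariates
debiased = dfgl.debias_pipeline(data, fit.B_hat, c=0.7)
for j in (0, 1, 2):
    s = dfgl.significance_statistic(debiased, j)
    h = dfgl.homogeneity_statistic(debiased, j)
    print(f"j={j}  sig p={s.p_value:.4f}  hom p={h.p_value:.4f}")
```

Output:

```
[0, 1]
j=0  sig p=0.0000  hom p=0.6522
j=1  sig p=0.0000  hom p=0.0000
j=2  sig p=0.9486  hom p=0.9669
```

Covariates 0 and 1 are selected and overwhelmingly significant;
the homogeneity test keeps the shared effect (j=0, p=0.65), flags the
sign-flipped one (j=1, p<1e-4), and the null covariate j=2 is neither
significant nor heterogeneous.

The same pipeline is scriptable from the shell: `dfgl fit`,
`dfgl debias`, `dfgl test`, and `dfgl simulate` (Monte-Carlo
power/type-I tables); `dfgl --help` lists options.

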