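"""Chi-squared tests on the debiased coefficients, and error-rate summaries.

For covariate j let ``b_(j)`` collect the G debiased coefficients and
``V_(j)`` their (diagonal) variance matrix with entries V^(g)_jj / n_g.

* Overall significance (is the covariate null in every group?):
  statistic ``b_(j)' V_(j)^{-1} b_(j)``, reference chi-squared with G
  degrees of freedom.
* Homogeneity (is the effect equal across groups?): with the first-
  difference contrast D (rows e_l - e_{l+1}), statistic
  ``b_(j)' D' (D V_(j) D')^{-1} D b_(j)``, chi-squared with G-1 df.
  Any full-rank difference basis T D gives the same quadratic form.

Multiple testing across j uses the Holm step-down adjustment, which
controls the familywise error rate (FWER).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .debias import DebiasedFit

__all__ = [
    "TestResult",
    "contrast_matrix",
    "significance_statistic",
    "homogeneity_statistic",
    "test_all",
    "holm_adjust",
    "fwer_power",
]


def contrast_matrix(G: int) -> np.ndarray:
    """The (G-1) x G first-difference contrast D: D 1_G = 0, rank G-1."""
    if G < 2:
        raise ValueError("contrast requires at least 2 groups")
    D = np.zeros((G - 1, G))
    for l in range(G - 1):
        D[l, l] = 1.0
        D[l, l + 1] = -1.0
    return D


@dataclass
class TestResult:
    """One covariate's test: statistic, degrees of freedom, p-value."""

    feature: int
    kind: str  # "significance" | "homogeneity"
    statistic: float
    df: int
    p_value: float
    reject_at: dict[float, bool] = field(default_factory=dict)


def _variance_row(debiased: DebiasedFit, j: int) -> np.ndarray:
    var = debiased.variance_row(j)
    if np.any(var <= 0):
        raise FloatingPointError(f"degenerate variance for feature {j}")
    return var


def significance_statistic(
    debiased: DebiasedFit,
    j: int,
    alphas: tuple[float, ...] = (0.05,),
    null_value: float = 0.0,
) -> TestResult:
    """Chi-squared (df G) test that covariate j is null in every group.

    ``null_value`` shifts the tested common value (the "= c" variant of
    the pointwise hypothesis); the default 0 is the significance test.
    """
    b = debiased.b_hat[j, :] - null_value
    var = _variance_row(debiased, j)
    stat = float(np.sum(b * b / var))
    G = debiased.n_groups
    pval = float(stats.chi2.sf(stat, G))
    return TestResult(
        feature=j,
        kind="significance",
        statistic=stat,
        df=G,
        p_value=pval,
        reject_at={a: stat > stats.chi2.isf(a, G) for a in alphas},
    )


def homogeneity_statistic(
    debiased: DebiasedFit, j: int, alphas: tuple[float, ...] = (0.05,)
) -> TestResult:
    """Chi-squared (df G-1) test of equal effects of covariate j across groups."""
    G = debiased.n_groups
    if G < 2:
        raise ValueError("homogeneity undefined for a single group")
    b = debiased.b_hat[j, :]
    var = _variance_row(debiased, j)
    D = contrast_matrix(G)
    Db = D @ b
    DVD = D @ np.diag(var) @ D.T
    try:
        sol = np.linalg.solve(DVD, Db)
    except np.linalg.LinAlgError as exc:
        raise FloatingPointError(f"singular D V D' for feature {j}") from exc
    stat = float(Db @ sol)
    pval = float(stats.chi2.sf(stat, G - 1))
    return TestResult(
        feature=j,
        kind="homogeneity",
        statistic=stat,
        df=G - 1,
        p_value=pval,
        reject_at={a: stat > stats.chi2.isf(a, G - 1) for a in alphas},
    )


def test_all(
    debiased: DebiasedFit,
    kind: str = "significance",
    alpha: float = 0.05,
) -> list[TestResult]:
    """Run the requested test for every covariate, in feature order."""
    if kind == "significance":
        return [
            significance_statistic(debiased, j, alphas=(alpha,))
            for j in range(debiased.n_features)
        ]
    if kind == "homogeneity":
        return [
            homogeneity_statistic(debiased, j, alphas=(alpha,))
            for j in range(debiased.n_features)
        ]
    raise ValueError(f"unknown test kind: {kind!r}")


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (FWER control), original order."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="holm")[1]


def fwer_power(
    decisions: np.ndarray, truth_set: set[int] | list[int]
) -> tuple[float, float]:
    """Familywise error rate and average power over Monte-Carlo replicates.

    ``decisions`` is an (M, p) boolean array of rejections;
    ``truth_set`` holds the indices where the null is false.  FWER is the
    fraction of replicates with at least one rejection outside the truth
    set; power averages, per replicate, the fraction of the truth set
    rejected.
    """
    decisions = np.asarray(decisions, dtype=bool)
    if decisions.ndim != 2:
        raise ValueError("decisions must be (replicates, features)")
    p = decisions.shape[1]
    truth = sorted(int(j) for j in truth_set)
    if any(j < 0 or j >= p for j in truth):
        raise ValueError("truth set index out of range")
    if not truth:
        raise ValueError("power undefined for an empty truth set")
    truth_mask = np.zeros(p, dtype=bool)
    truth_mask[truth] = True
    fwer = float(np.mean(decisions[:, ~truth_mask].any(axis=1))) if p > len(truth) else 0.0
    power = float(np.mean(decisions[:, truth_mask].mean(axis=1)))
    return fwer, power
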