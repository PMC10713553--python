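"""Drug-response binarization and two-stage gene screening.

Pharmacogenomic cell-line screens report a continuous potency value
(IC50) per cell line; a line is called "sensitive" (coded 1) when IC50
falls below a threshold, "resistant" (0) otherwise.  Because expression
panels are ultra-high-dimensional, the covariates are reduced before
model fitting: stage one keeps the K1 columns with the largest sample
variances, stage two fits a marginal logistic regression of the response
on each kept column plus cancer-type dummies and keeps the K2 columns
with the smallest Wald p-values.

Ties in either ranking are broken toward the lowest column index, so the
screen is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["ScreeningResult", "binarize_response", "screen_features"]


def binarize_response(values, threshold: float = 0.5) -> np.ndarray:
    """1 ("sensitive") where ``value < threshold``, else 0 ("resistant")."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("response values must be finite")
    return (values < threshold).astype(int)


@dataclass
class ScreeningResult:
    """Outcome of the variance + marginal-p-value screen.

    ``final_kept`` is a subset of ``variance_kept``; ``marginal_pvalues``
    maps each variance-kept column index to its Wald p-value.
    """

    variance_kept: list[int]
    final_kept: list[int]
    marginal_pvalues: dict[int, float]


def _marginal_pvalue(x: np.ndarray, y: np.ndarray, dummies: np.ndarray | None) -> float:
    """Wald p-value of x in logit(y ~ 1 + x + dummies); 1.0 on separation."""
    cols = [np.ones_like(x), x]
    if dummies is not None:
        cols.extend(dummies.T)
    design = np.column_stack(cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        pval = float(res.pvalues[1])
        if not np.isfinite(pval):
            raise ValueError("non-finite p-value")
    except Exception:
        warnings.warn(
            "perfect separation or non-convergence in marginal fit; "
            "recording conservative p-value 1",
            RuntimeWarning,
            stacklevel=3,
        )
        return 1.0
    return pval


def screen_features(
    X: np.ndarray,
    y: np.ndarray,
    group_labels: np.ndarray | None,
    K1: int,
    K2: int,
) -> ScreeningResult:
    """Two-stage screen: top-K1 by variance, then top-K2 by marginal p-value.

    Parameters
    ----------
    X
        Full ``(n, p)`` covariate matrix (all groups stacked).
    y
        Binary response of length n.
    group_labels
        Group label per row; G-1 treatment-coded dummies enter each
        marginal fit.  ``None`` fits without dummies.
    K1, K2
        Stage sizes, ``K2 <= K1 <= p``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not (1 <= K2 <= K1 <= p):
        raise ValueError("need 1 <= K2 <= K1 <= p")

    variances = X.var(axis=0, ddof=1)
    # descending variance, ties -> lowest index first
    order = np.lexsort((np.arange(p), -variances))
    variance_kept = sorted(int(j) for j in order[:K1])

    dummies = None
    if group_labels is not None:
        labels = np.asarray(group_labels)
        levels = np.unique(labels)
        if levels.size < 2:
            raise ValueError("group dummies require at least 2 groups")
        dummies = np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])

    pvals = {j: _marginal_pvalue(X[:, j], y, dummies) for j in variance_kept}
    kept_arr = np.array(variance_kept)
    pv_arr = np.array([pvals[j] for j in variance_kept])
    order2 = np.lexsort((kept_arr, pv_arr))  # ascending p, ties -> lowest index
    final_kept = sorted(int(kept_arr[i]) for i in order2[: min(K2, len(variance_kept))])
    return ScreeningResult(variance_kept, final_kept, pvals)
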