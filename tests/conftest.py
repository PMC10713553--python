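import numpy as np
import pytest

from dfgl import CoefficientMatrix, standardize
from scipy.special import expit


def make_grouped(
    seed: int,
    group_sizes=(40, 40, 40),
    p: int = 5,
    beta: np.ndarray | None = None,
    rho: float = 0.0,
):
    """Small standardized logistic dataset, optionally AR(rho) covariates."""
    rng = np.random.default_rng(seed)
    G = len(group_sizes)
    if beta is None:
        beta = np.zeros((p, G))
    raw, ys = [], []
    for g, n_g in enumerate(group_sizes):
        X = rng.standard_normal((n_g, p))
        if rho:
            idx = np.arange(p)
            L = np.linalg.cholesky(rho ** np.abs(idx[:, None] - idx[None, :]))
            X = X @ L.T
        nu = X @ beta[:, g]
        ys.append((rng.random(n_g) < expit(nu)).astype(float))
        raw.append(X)
    data, record = standardize(raw, ys)
    return data, record, CoefficientMatrix(beta)


@pytest.fixture
def toy_null():
    """3 groups, p=5, no signal."""
    data, record, truth = make_grouped(0)
    return data


@pytest.fixture
def toy_signal():
    """3 groups of 60, p=6, one strong homogeneous row."""
    beta = np.zeros((6, 3))
    beta[0] = 1.2
    data, _, _ = make_grouped(1, group_sizes=(60, 60, 60), p=6, beta=beta)
    return data
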