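"""Independent reference solvers used only by the tests.

These deliberately avoid the package's own ADMM / coordinate-descent
routes: the penalized fit is checked against an L-BFGS-B minimization of
a pseudo-Huber smoothing of the penalty (smoothing bias bounded
analytically), and the decorrelation QP against SLSQP on the constrained
problem itself.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from dfgl.losses import neg_loglik
from dfgl.solver import PenaltySpec, fusion_matrix


def smoothed_fgl_objective_min(
    data, penalty: PenaltySpec, x0: np.ndarray | None = None, eps: float = 1e-7
) -> tuple[float, np.ndarray]:
    """Minimize L_n + smoothed penalty; returns (true objective at argmin, argmin).

    The pseudo-Huber smoothing sqrt(x^2 + eps^2) overestimates |x| by at
    most eps per term, so the returned objective is within
    eps * (lambda1 * sum w + lambda2 * sum v) of the true minimum.
    """
    p, G = data.n_features, data.n_groups
    H = fusion_matrix(G) if G >= 2 else np.zeros((1, 0))

    def obj(x):
        B = x.reshape(p, G)
        val = neg_loglik(data, B)
        rn = np.sqrt((B * B).sum(axis=1) + eps**2)
        val += penalty.lambda1 * float(penalty.w @ rn)
        if H.shape[1]:
            d = B @ H
            val += penalty.lambda2 * float(
                np.sum(penalty.v * np.sqrt(d * d + eps**2))
            )
        return val

    x0 = np.zeros(p * G) if x0 is None else np.asarray(x0).ravel()
    res = minimize(
        obj, x0, method="L-BFGS-B",
        options={"maxiter": 50000, "maxfun": 200000, "ftol": 1e-15, "gtol": 1e-10},
    )
    from dfgl.solver import penalized_objective

    B = res.x.reshape(p, G)
    return penalized_objective(data, B, penalty), B


def qp_decorrelation_oracle(Sigma: np.ndarray, j: int, mu: float):
    """SLSQP solve of min 1/2 m'Sm s.t. ||Sm - e_j||_max <= mu."""
    p = Sigma.shape[0]
    e = np.zeros(p)
    e[j] = 1.0
    cons = LinearConstraint(Sigma, e - mu, e + mu)
    x0 = np.linalg.solve(Sigma + 1e-8 * np.eye(p), e)
    res = minimize(
        lambda x: 0.5 * x @ Sigma @ x,
        x0,
        jac=lambda x: Sigma @ x,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return res.fun, res.x
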