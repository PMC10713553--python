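"""Synthetic data generators and the Monte-Carlo experiment runner.

Covariates are drawn i.i.d. multivariate normal with either an AR(1)
correlation (entry ``0.5^|i-j|``) or a block-diagonal covariance made of
4 x 4 Toeplitz(0.5) blocks; responses are Bernoulli with logistic link.
Two study designs are built in:

* ``balanced``: G = 7 equal groups, a coefficient matrix whose first 12
  rows mix heterogeneous rows (sign flips of 0.6/0.4 in rows 1-4),
  homogeneous signal rows (0.4, -0.4, 1.5, 2.5) and null rows.
* ``imbalanced``: G = 3 groups of sizes (90, 70, 40), p = 300, six
  active rows at fixed indices, four of them heterogeneous.

Each replicate seeds its own generator as ``base_seed XOR rep``, so any
table cell is a pure function of (scenario, base_seed) and replicates
can be recomputed independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CoefficientMatrix, GroupedDataset, standardize
from .debias import debias_pipeline
from .inference import holm_adjust, test_all
from .solver import CVSpec, SolverConfig, fit_dfgl_two_stage

__all__ = [
    "ScenarioSpec",
    "ExperimentTable",
    "make_covariance",
    "balanced_beta",
    "imbalanced_beta",
    "balanced_scenario",
    "imbalanced_scenario",
    "simulate_dataset",
    "run_experiment",
    "IMBALANCED_GROUP_SIZES",
]

IMBALANCED_GROUP_SIZES = (90, 70, 40)


def make_covariance(p: int, kind: str = "ar1") -> np.ndarray:
    """Covariate covariance: "ar1" -> 0.5^|i-j|; "block" -> 4x4 Toeplitz blocks."""
    if kind == "ar1":
        idx = np.arange(p)
        return 0.5 ** np.abs(idx[:, None] - idx[None, :])
    if kind == "block":
        if p % 4 != 0:
            raise ValueError("block covariance requires p divisible by 4")
        idx = np.arange(4)
        block = 0.5 ** np.abs(idx[:, None] - idx[None, :])
        out = np.zeros((p, p))
        for b in range(p // 4):
            out[4 * b : 4 * b + 4, 4 * b : 4 * b + 4] = block
        return out
    raise ValueError(f"unknown covariance kind: {kind!r}")


def balanced_beta(p: int) -> CoefficientMatrix:
    """The balanced-design truth: G = 7, 12 structured rows, rest zero."""
    if p < 12:
        raise ValueError("balanced truth needs p >= 12")
    B = np.zeros((p, 7))
    B[0] = (-0.6, -0.6, 0.6, 0.6, 0.6, 0.6, 0.6)
    B[1] = (0.6, 0.6, -0.6, -0.6, 0.6, 0.6, 0.6)
    B[2] = (0.6, 0.6, 0.6, 0.6, -0.4, -0.4, 0.6)
    B[3] = (-0.4, 0.6, 0.6, 0.6, 0.6, 0.6, -0.4)
    B[4] = 0.4
    # rows 6, 7 (1-based) are zero
    B[7] = -0.4
    B[8] = 1.5
    B[9] = 1.5
    # row 11 (1-based) zero
    B[11] = 2.5
    return CoefficientMatrix(B)


def imbalanced_beta() -> CoefficientMatrix:
    """The imbalanced-design truth: G = 3, p = 300, six active rows."""
    B = np.zeros((300, 3))
    B[84] = (1.5, 1.5, 1.5)
    B[128] = (2.0, 2.0, 2.0)
    B[166] = (1.0, 1.0, -1.0)
    B[186] = (-1.0, 1.0, 1.0)
    B[210] = (0.8, 0.8, -0.8)
    B[269] = (0.8, -0.8, 0.8)
    return CoefficientMatrix(B)


@dataclass
class ScenarioSpec:
    """A fully specified simulation scenario."""

    G: int
    p: int
    group_sizes: tuple[int, ...]
    covariance_kind: str
    true_B: CoefficientMatrix
    reps: int
    base_seed: int
    alpha: float = 0.05
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.group_sizes) != self.G:
            raise ValueError("group_sizes length must equal G")
        if self.true_B.values.shape != (self.p, self.G):
            raise ValueError("true_B shape must be (p, G)")
        if self.reps < 1:
            raise ValueError("reps must be positive")

    @property
    def significance_truth(self) -> set[int]:
        """Rows with a nonzero effect in some group (significance alternatives)."""
        return {
            int(j)
            for j in np.flatnonzero(np.linalg.norm(self.true_B.values, axis=1) > 0)
        }

    @property
    def homogeneity_truth(self) -> set[int]:
        """Rows with non-constant effects across groups (heterogeneity)."""
        B = self.true_B.values
        return {int(j) for j in np.flatnonzero(B.max(axis=1) - B.min(axis=1) > 0)}


def balanced_scenario(
    covariance_kind: str = "ar1",
    m: int = 200,
    p: int = 80,
    reps: int = 100,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> ScenarioSpec:
    """Balanced design: G = 7 groups of size m each."""
    return ScenarioSpec(
        G=7,
        p=p,
        group_sizes=(m,) * 7,
        covariance_kind=covariance_kind,
        true_B=balanced_beta(p),
        reps=reps,
        base_seed=base_seed,
        alpha=alpha,
        name=f"balanced-{covariance_kind}",
    )


def imbalanced_scenario(
    reps: int = 100, base_seed: int = 0, alpha: float = 0.05
) -> ScenarioSpec:
    """Imbalanced design: G = 3, n = (90, 70, 40), p = 300, AR(1)."""
    return ScenarioSpec(
        G=3,
        p=300,
        group_sizes=IMBALANCED_GROUP_SIZES,
        covariance_kind="ar1",
        true_B=imbalanced_beta(),
        reps=reps,
        base_seed=base_seed,
        alpha=alpha,
        name="imbalanced",
    )


def simulate_dataset(
    spec: ScenarioSpec, rep: int, return_raw: bool = False
):
    """One replicate's dataset: Gaussian covariates, Bernoulli responses.

    The generator is seeded as ``base_seed XOR rep`` so replicates are
    reproducible independently.  Designs are standardized after
    generation; pass ``return_raw=True`` to also get the raw designs.
    """
    rng = np.random.default_rng((spec.base_seed ^ rep) & 0x7FFFFFFF)
    Sigma = make_covariance(spec.p, spec.covariance_kind)
    L = np.linalg.cholesky(Sigma)
    raw, responses = [], []
    for g in range(spec.G):
        n_g = spec.group_sizes[g]
        X = rng.standard_normal((n_g, spec.p)) @ L.T
        nu = X @ spec.true_B.values[:, g]
        y = (rng.random(n_g) < expit(nu)).astype(float)
        raw.append(X)
        responses.append(y)
    data, record = standardize(raw, responses)
    if return_raw:
        return data, raw, record
    return data


@dataclass
class ExperimentTable:
    """Per-feature rejection frequencies and multiple-testing summaries."""

    spec: ScenarioSpec
    rates: dict[str, np.ndarray]
    fwer: dict[str, float] = field(default_factory=dict)
    power: dict[str, float] = field(default_factory=dict)
    reps_used: int = 0
    redraws: int = 0

    def rate(self, kind: str, j: int) -> float:
        return float(self.rates[kind][j])

    def to_dataframe(self, feature_sets: dict[str, list[int]] | None = None) -> pd.DataFrame:
        rows = []
        M = self.reps_used
        for kind, rates in self.rates.items():
            js = (
                feature_sets.get(kind, range(len(rates)))
                if feature_sets
                else range(len(rates))
            )
            for j in js:
                r = float(rates[j])
                rows.append(
                    {
                        "scenario": self.spec.name,
                        "test": kind,
                        "j": int(j) + 1,  # 1-based in reports
                        "rate": r,
                        "stderr": float(np.sqrt(r * (1 - r) / M)) if M else np.nan,
                        "M": M,
                    }
                )
        return pd.DataFrame(rows)


def run_experiment(
    spec: ScenarioSpec,
    test_kinds: tuple[str, ...] = ("significance", "homogeneity"),
    config: SolverConfig | None = None,
    cv: CVSpec | None = None,
    c: float = 0.7,
    multiple_testing: bool = False,
    max_failure_frac: float = 0.05,
) -> ExperimentTable:
    """Monte-Carlo rejection rates of the full pipeline on a scenario.

    Per replicate: simulate, two-stage CV fit, debias, test all features
    at ``spec.alpha``; in multiple-testing mode the per-feature p-values
    are Holm-adjusted and FWER/power are measured against the scenario's
    truth sets.  Failed replicates are redrawn with a shifted seed; more
    than ``max_failure_frac`` failures aborts.
    """
    if config is None:
        config = SolverConfig(step_rule="spectral")
    if cv is None:
        cv = CVSpec()
    M, p = spec.reps, spec.p
    reject = {kind: np.zeros((M, p), dtype=bool) for kind in test_kinds}
    reject_mt = {kind: np.zeros((M, p), dtype=bool) for kind in test_kinds}
    redraws = 0
    max_failures = max(1, int(np.ceil(max_failure_frac * M)))
    for rep in range(M):
        rep_id = rep
        while True:
            try:
                data = simulate_dataset(spec, rep_id)
                _, final = fit_dfgl_two_stage(data, config, cv)
                debiased = debias_pipeline(data, final.B_hat, c=c)
                for kind in test_kinds:
                    results = test_all(debiased, kind=kind, alpha=spec.alpha)
                    pvals = np.array([r.p_value for r in results])
                    reject[kind][rep] = pvals < spec.alpha
                    if multiple_testing:
                        reject_mt[kind][rep] = holm_adjust(pvals) < spec.alpha
                break
            except Exception as exc:  # noqa: BLE001 - per-replicate guard
                redraws += 1
                if redraws > max_failures:
                    raise RuntimeError(
                        f"more than {max_failures} failed replicates"
                    ) from exc
                warnings.warn(
                    f"replicate {rep} failed ({exc}); redrawing with shifted seed",
                    RuntimeWarning,
                    stacklevel=2,
                )
                rep_id += 1009 * M + 1  # disjoint from the regular rep range

    table = ExperimentTable(
        spec=spec,
        rates={kind: reject[kind].mean(axis=0) for kind in test_kinds},
        reps_used=M,
        redraws=redraws,
    )
    if multiple_testing:
        for kind in test_kinds:
            truth = (
                spec.significance_truth
                if kind == "significance"
                else spec.homogeneity_truth
            )
            from .inference import fwer_power

            fw, pw = fwer_power(reject_mt[kind], truth)
            table.fwer[kind] = fw
            table.power[kind] = pw
    return table
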