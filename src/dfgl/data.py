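"""Grouped data containers and per-group column standardization.

The model stratifies the sample into ``G`` independent subpopulations
(e.g. cancer types), each with its own design matrix ``X^(g)`` of shape
``(n_g, p)`` and binary response ``y^(g)``.  All downstream estimation
assumes every column of every ``X^(g)`` has mean zero and Euclidean norm
``sqrt(n_g)``; :func:`standardize` produces that scaling and records how
to undo it.

There is deliberately no intercept in the model: responses are used
as-is and designs are centered within each group.  Users expecting an
intercept term should be aware that the fitted coefficients describe
log-odds relative to the group-wise covariate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroupedDataset",
    "CoefficientMatrix",
    "StandardizationRecord",
    "standardize",
]

_STD_TOL = 1e-10


@dataclass
class CoefficientMatrix:
    """A ``p x G`` matrix of group-specific regression coefficients.

    Column ``g`` is the coefficient vector of group ``g``; row ``j`` collects
    the effects of covariate ``j`` across the ``G`` groups.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("coefficient matrix must be two-dimensional (p, G)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficient matrix contains non-finite entries")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n_groups(self) -> int:
        return self.values.shape[1]

    def column(self, g: int) -> np.ndarray:
        """Coefficient vector beta^(g) of group ``g``."""
        return self.values[:, g]

    def row(self, j: int) -> np.ndarray:
        """Cross-group effect vector beta_(j) of covariate ``j``."""
        return self.values[j, :]


@dataclass
class GroupedDataset:
    """Per-group designs and binary responses.

    Attributes
    ----------
    designs
        List of ``G`` arrays of shape ``(n_g, p)``.
    responses
        List of ``G`` arrays of shape ``(n_g,)`` with entries in {0, 1}.
    standardized
        True when every design column has mean 0 and norm ``sqrt(n_g)``.
    """

    designs: list[np.ndarray]
    responses: list[np.ndarray]
    standardized: bool = False

    def __post_init__(self) -> None:
        if len(self.designs) == 0:
            raise ValueError("dataset needs at least one group")
        if len(self.designs) != len(self.responses):
            raise ValueError("designs and responses must have the same length")
        self.designs = [np.ascontiguousarray(X, dtype=float) for X in self.designs]
        self.responses = [np.asarray(y, dtype=float).ravel() for y in self.responses]
        p = self.designs[0].shape[1]
        for g, (X, y) in enumerate(zip(self.designs, self.responses)):
            if X.ndim != 2 or X.shape[1] != p:
                raise ValueError(f"group {g}: design must have {p} columns")
            if X.shape[0] == 0:
                raise ValueError(f"group {g}: empty design")
            if y.shape[0] != X.shape[0]:
                raise ValueError(
                    f"group {g}: response length {y.shape[0]} != n_g {X.shape[0]}"
                )
            if not np.all(np.isin(y, (0.0, 1.0))):
                raise ValueError(f"group {g}: responses must be binary 0/1")

    @property
    def n_groups(self) -> int:
        return len(self.designs)

    @property
    def group_sizes(self) -> list[int]:
        return [X.shape[0] for X in self.designs]

    @property
    def total_n(self) -> int:
        return sum(self.group_sizes)

    @property
    def n_features(self) -> int:
        return self.designs[0].shape[1]

    def check_standardized(self) -> bool:
        """Verify the mean-0 / norm-sqrt(n_g) column invariants."""
        for X in self.designs:
            n_g = X.shape[0]
            if np.max(np.abs(X.mean(axis=0))) > _STD_TOL:
                return False
            norms = np.linalg.norm(X, axis=0)
            if np.max(np.abs(norms / np.sqrt(n_g) - 1.0)) > _STD_TOL:
                return False
        return True


@dataclass
class StandardizationRecord:
    """Per-group column centers and scales mapping raw to standardized data.

    ``standardized = (raw - center) / scale`` column-wise; scales are strictly
    positive so the transform is invertible.
    """

    centers: list[np.ndarray] = field(default_factory=list)
    scales: list[np.ndarray] = field(default_factory=list)

    def apply(self, raw_designs: list[np.ndarray]) -> list[np.ndarray]:
        return [
            (np.asarray(X, dtype=float) - c) / s
            for X, c, s in zip(raw_designs, self.centers, self.scales)
        ]

    def invert(self, std_designs: list[np.ndarray]) -> list[np.ndarray]:
        return [
            np.asarray(X, dtype=float) * s + c
            for X, c, s in zip(std_designs, self.centers, self.scales)
        ]


def standardize(
    raw_designs: list[np.ndarray],
    responses: list[np.ndarray] | None = None,
) -> tuple[GroupedDataset, StandardizationRecord]:
    """Center each column and rescale it to Euclidean norm ``sqrt(n_g)``.

    Parameters
    ----------
    raw_designs
        One ``(n_g, p)`` matrix per group.
    responses
        Optional binary responses; when omitted, zero placeholders are
        stored (useful when standardizing covariates ahead of response
        construction).

    Returns
    -------
    (GroupedDataset, StandardizationRecord)

    Raises
    ------
    ValueError
        If any column is constant within a group (zero scale).
    """
    record = StandardizationRecord()
    std = []
    for g, X in enumerate(raw_designs):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError(f"group {g}: design must be a nonempty 2-D matrix")
        n_g = X.shape[0]
        center = X.mean(axis=0)
        centered = X - center
        norms = np.linalg.norm(centered, axis=0)
        bad = np.flatnonzero(norms == 0.0)
        if bad.size:
            raise ValueError(
                f"constant column within a group: group {g}, column {int(bad[0])}"
            )
        scale = norms / np.sqrt(n_g)
        record.centers.append(center)
        record.scales.append(scale)
        std.append(centered / scale)
    if responses is None:
        responses = [np.zeros(X.shape[0]) for X in std]
    data = GroupedDataset(std, list(responses), standardized=True)
    if not data.check_standardized():  # pragma: no cover - numerical safety net
        raise AssertionError("standardization failed to meet tolerance")
    return data, record
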