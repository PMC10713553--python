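"""Delimited-text readers/writers for grouped designs and fit artifacts.

Two layouts are supported, both CSV/TSV with a header row:

* long — one file with columns ``group, y, x1..xp``;
* split — one design file and one response file per group (the response
  file has a single ``y`` column).

Matrices are written with 17 significant digits so a write/read
round-trip is exact for double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GroupedDataset
from .debias import DebiasedFit
from .solver import FGLFit

__all__ = [
    "read_long",
    "write_long",
    "read_split",
    "write_split",
    "fit_to_json",
    "fit_from_json",
    "debias_to_json",
]

_FLOAT_FMT = "%.17g"


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_long(path: str | Path) -> tuple[list[np.ndarray], list[np.ndarray], list]:
    """Read ``group, y, x1..xp`` rows; returns (designs, responses, labels)."""
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if "group" not in df.columns or "y" not in df.columns:
        raise ValueError("long format needs 'group' and 'y' columns")
    xcols = [c for c in df.columns if c not in ("group", "y")]
    designs, responses, labels = [], [], []
    for label, sub in df.groupby("group", sort=True):
        designs.append(sub[xcols].to_numpy(dtype=float))
        responses.append(sub["y"].to_numpy(dtype=float))
        labels.append(label)
    return designs, responses, labels


def write_long(
    path: str | Path,
    designs: list[np.ndarray],
    responses: list[np.ndarray],
    labels: list | None = None,
) -> None:
    if labels is None:
        labels = list(range(len(designs)))
    frames = []
    p = designs[0].shape[1]
    for label, X, y in zip(labels, designs, responses):
        df = pd.DataFrame(X, columns=[f"x{j+1}" for j in range(p)])
        df.insert(0, "y", y)
        df.insert(0, "group", label)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT
    )


def read_split(
    design_paths: list[str | Path], response_paths: list[str | Path]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Read one design file and one single-column response file per group."""
    if len(design_paths) != len(response_paths):
        raise ValueError("need one response file per design file")
    designs = [
        pd.read_csv(p, sep=_sep_for(p), float_precision="round_trip").to_numpy(dtype=float)
        for p in design_paths
    ]
    responses = [
        pd.read_csv(p, sep=_sep_for(p), float_precision="round_trip").iloc[:, 0].to_numpy(dtype=float)
        for p in response_paths
    ]
    return designs, responses


def write_split(
    design_paths: list[str | Path],
    response_paths: list[str | Path],
    designs: list[np.ndarray],
    responses: list[np.ndarray],
) -> None:
    p = designs[0].shape[1]
    for dp, rp, X, y in zip(design_paths, response_paths, designs, responses):
        pd.DataFrame(X, columns=[f"x{j+1}" for j in range(p)]).to_csv(
            dp, sep=_sep_for(dp), index=False, float_format=_FLOAT_FMT
        )
        pd.DataFrame({"y": y}).to_csv(
            rp, sep=_sep_for(rp), index=False, float_format=_FLOAT_FMT
        )


def fit_to_json(fit: FGLFit, path: str | Path, extra: dict | None = None) -> None:
    payload = {
        "B_hat": fit.B_hat.values.tolist(),
        "S_hat": sorted(fit.S_hat),
        "Omega_hat": sorted(list(t) for t in fit.Omega_hat),
        "lambda1": fit.penalty.lambda1,
        "lambda2": fit.penalty.lambda2,
        "objective": fit.objective_value,
        "iterations_used": fit.iterations_used,
        "converged": fit.converged,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def fit_from_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def debias_to_json(
    debiased: DebiasedFit,
    path: str | Path,
    mu_used: list[np.ndarray] | None = None,
    full_variance: bool = False,
) -> None:
    payload: dict = {
        "b_hat": debiased.b_hat.tolist(),
        "group_sizes": list(debiased.group_sizes),
        "V_diag": [np.diag(V).tolist() for V in debiased.V_g],
    }
    if mu_used is not None:
        payload["mu_used"] = [np.asarray(m).tolist() for m in mu_used]
    if full_variance:
        payload["V_full"] = [V.tolist() for V in debiased.V_g]
    Path(path).write_text(json.dumps(payload, indent=1))


def dataset_from_files(
    fmt: str,
    data_path: str | Path | None = None,
    design_paths: list[str | Path] | None = None,
    response_paths: list[str | Path] | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Dispatch reader for the CLI's --format long|split."""
    if fmt == "long":
        designs, responses, _ = read_long(data_path)
        return designs, responses
    if fmt == "split":
        return read_split(design_paths or [], response_paths or [])
    raise ValueError(f"unknown format: {fmt!r}")


def debiased_from_json(path: str | Path) -> DebiasedFit:
    """Rebuild a DebiasedFit written with full variance matrices."""
    payload = json.loads(Path(path).read_text())
    if "V_full" in payload:
        V_g = [np.asarray(V, dtype=float) for V in payload["V_full"]]
    else:
        V_g = [np.diag(np.asarray(d, dtype=float)) for d in payload["V_diag"]]
    return DebiasedFit(
        b_hat=np.asarray(payload["b_hat"], dtype=float),
        V_g=V_g,
        group_sizes=list(payload["group_sizes"]),
    )
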