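"""Reference-based leukocyte deconvolution (constrained projection).

Estimates six blood-cell-type proportions per sample from methylation at
cell-type-discriminating marker CpGs, in the spirit of reference-based
deconvolution of whole-blood arrays: for each sample with marker betas
``y`` and a reference profile matrix ``X`` (markers x cell types), solve

    minimize  || y - X w ||^2    subject to  w >= 0,  sum(w) <= 1.

Both the raw constrained solution and a renormalized version (w / sum(w),
reported proportions summing to 1) are returned; downstream regression uses
the renormalized proportions by default.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datasets import MethylationDataset
from .synthdata import CellReference

FEASIBILITY_TOL = 1e-8


@dataclasses.dataclass
class CellProportions:
    """Per-sample cell-type fractions: raw constrained fit and renormalized."""

    raw: pd.DataFrame  # samples x cell types, w >= 0, sum <= 1 (+tol)
    renormalized: pd.DataFrame  # rows sum to 1

    @property
    def cell_types(self):
        return list(self.raw.columns)


def _solve_constrained(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Nonnegative least squares with a simplex inequality, one sample."""
    k = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y

    def objective(w):
        r = XtX @ w - Xty
        return float(w @ XtX @ w / 2.0 - Xty @ w), r

    w0 = np.full(k, 1.0 / (k + 1))
    res = minimize(
        objective,
        w0,
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones(k)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    if w.sum() > 1.0 + FEASIBILITY_TOL:
        w = w / w.sum()
    return w


def estimate_proportions(
    dataset: MethylationDataset, reference: CellReference
) -> CellProportions:
    """Estimate cell proportions for every sample in the dataset.

    Raises
    ------
    ValueError
        If any reference marker probe is absent from the dataset (the
        offending probes are listed).
    """
    markers = reference.marker_probe_ids
    missing = [p for p in markers if p not in dataset.betas.columns]
    if missing:
        raise ValueError(f"marker probes missing from dataset: {missing}")
    X = reference.profiles.to_numpy(dtype=float)
    Y = dataset.betas.loc[:, markers].to_numpy(dtype=float)
    W = np.vstack([_solve_constrained(X, y) for y in Y])
    raw = pd.DataFrame(W, index=dataset.betas.index, columns=reference.cell_types)
    sums = W.sum(axis=1)
    safe = np.where(sums > 0, sums, 1.0)
    renorm = pd.DataFrame(
        W / safe[:, None], index=raw.index, columns=raw.columns
    )
    return CellProportions(raw=raw, renormalized=renorm)
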