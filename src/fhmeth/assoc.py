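"""Correlation of methylation with expression or phenotype variables.

A local stand-in for database lookups of methylation-expression
correlations: given paired vectors (e.g. a probe's betas and a gene's
expression, or a phenotype such as triglyceride level), compute Pearson
and/or Spearman correlations with two-sided p-values, and flag pairs as
suggestively biologically relevant when p < 0.05 and |r| > 0.1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass(frozen=True)
class Correlation:
    r: float
    p: float
    n: int
    method: str
    degenerate: bool = False  # zero variance in an input: r undefined


def correlate(x_values, y_values, method: str = "spearman") -> Correlation:
    """Pearson or Spearman correlation on pairwise-complete observations.

    Spearman uses average ranks for ties; p-values are two-sided via the
    t approximation on r.  Requires >= 3 complete pairs.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return Correlation(np.nan, np.nan, n, method, degenerate=True)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return Correlation(float(r), float(p), n, method)


def filter_biological(
    results: pd.DataFrame,
    p_threshold: float = 0.05,
    r_threshold: float = 0.1,
) -> pd.DataFrame:
    """Flag correlations as suggestively biologically relevant.

    A pair is flagged when p < ``p_threshold`` and |r| > ``r_threshold``
    (the magnitude rule: strong negative correlations count too).  Expects
    columns ``r`` and ``p``; returns a copy with a ``biologically_relevant``
    boolean column.
    """
    out = results.copy()
    out["biologically_relevant"] = (out["p"] < p_threshold) & (
        out["r"].abs() > r_threshold
    )
    return out


def correlate_probes(
    betas: pd.DataFrame,
    variables: pd.DataFrame,
    methods=("pearson", "spearman"),
) -> pd.DataFrame:
    """All (probe, variable) correlations on shared samples.

    ``betas``: samples x probes; ``variables``: samples x variables
    (expression values or phenotypes), joined on sample id.
    """
    shared = betas.index.intersection(variables.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between tables")
    rows = []
    for probe in betas.columns:
        for var in variables.columns:
            for method in methods:
                c = correlate(betas.loc[shared, probe], variables.loc[shared, var], method)
                rows.append(
                    {
                        "probe_id": probe,
                        "variable": var,
                        "method": method,
                        "r": c.r,
                        "p": c.p,
                        "n": c.n,
                        "degenerate": c.degenerate,
                    }
                )
    return pd.DataFrame(rows)
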