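"""Per-CpG differential methylation statistics.

For every probe, methylation (beta values by default, M-values optionally)
is regressed on group (FH mutation-negative vs mutation-positive), age, and
estimated leukocyte proportions.  The reported effect ``beta_hat`` is the
group coefficient, mutation-negative minus mutation-positive, in the units
of the modeling scale (so on the beta scale, -0.013 is a 1.3-percentage-
point lower methylation in mutation-negative samples).

Three post-processing stages follow the fit:

* empirical-Bayes variance moderation — residual variances are shrunk
  toward a pooled prior fitted by method of moments on log variances
  (scaled inverse-chi-square prior with d0 degrees of freedom and scale
  s0^2), giving moderated t statistics with df + d0 degrees of freedom;
* empirical-null inflation correction — a three-component Gaussian mixture
  (null N(mu0, sigma0^2) plus two symmetric tail components at mu0 +/- mu1)
  is fitted to the z-scores by EM; corrected z = (z - mu0) / sigma0 removes
  bias and inflation of the test-statistic distribution.  The genomic
  inflation factor lambda = median(z^2) / 0.4549 is reported alongside;
* Benjamini-Hochberg FDR over the corrected p-values.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import MethylationDataset
from .deconv import CellProportions
from .qc import beta_to_m

logger = logging.getLogger(__name__)

#: expectation of the squared z under the null, median(chi2_1)
CHI2_MEDIAN = 0.4549

#: largest blood fraction; dropped from the design to keep the cell
#: proportions (which sum to 1) from being collinear with the intercept
DEFAULT_DROPPED_CELL_TYPE = "Gran"


@dataclasses.dataclass
class DmpResult:
    """Per-probe regression table plus fit metadata.

    ``table`` columns: beta_hat, se, t, df, p_raw (ordinary fit);
    t_moderated, df_moderated, p_moderated (after variance moderation);
    z, p_corrected, q (after inflation correction and FDR);
    degenerate (zero-variance probes, excluded from inference).
    """

    table: pd.DataFrame
    scale: str
    stdev_unscaled: pd.Series  # sqrt of the group-coefficient's (X'X)^-1 entry
    prior_df: float | None = None
    prior_var: float | None = None

    def probes(self):
        return list(self.table.index)

    def subset(self, probe_ids) -> "DmpResult":
        probe_ids = [p for p in probe_ids if p in self.table.index]
        return DmpResult(
            table=self.table.loc[probe_ids].copy(),
            scale=self.scale,
            stdev_unscaled=self.stdev_unscaled.loc[probe_ids],
            prior_df=self.prior_df,
            prior_var=self.prior_var,
        )


@dataclasses.dataclass
class InflationFit:
    """Empirical-null parameters of the z-score distribution."""

    mu0: float
    sigma0: float
    pi0: float
    mu1: float
    sigma1: float
    lambda_gc: float
    converged: bool
    method: str  # "em", "identity", or "median_mad"


class DesignError(ValueError):
    """Raised when the regression design matrix is rank deficient."""


def _build_design(
    dataset: MethylationDataset,
    proportions: CellProportions | None,
    drop_cell_type: str = DEFAULT_DROPPED_CELL_TYPE,
    use_raw_proportions: bool = False,
    include_age: bool = True,
) -> tuple[np.ndarray, list]:
    cols = {"intercept": np.ones(dataset.n_samples)}
    cols["group_neg"] = dataset.group_mask_neg.astype(float)
    if include_age:
        cols["age"] = dataset.samples["age"].to_numpy(dtype=float)
    if proportions is not None:
        props = proportions.raw if use_raw_proportions else proportions.renormalized
        for ct in props.columns:
            if ct == drop_cell_type:
                continue
            cols[ct] = props[ct].to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for i, name in enumerate(names):
            if name == "intercept":
                continue
            reduced = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
                bad.append(name)
        raise DesignError(f"design matrix rank deficient; collinear columns: {bad}")
    return X, names


def fit_dmp(
    dataset: MethylationDataset,
    proportions: CellProportions | None = None,
    scale: str = "beta",
    drop_cell_type: str = DEFAULT_DROPPED_CELL_TYPE,
    use_raw_proportions: bool = False,
    include_age: bool = True,
) -> DmpResult:
    """Ordinary least squares per probe, group effect adjusted for covariates.

    ``scale='beta'`` regresses beta values directly (effects in methylation-
    fraction units); ``scale='m'`` regresses M-values.  ``include_age=False``
    fits the two-group comparison without the age covariate.
    """
    if scale not in ("beta", "m"):
        raise ValueError("scale must be 'beta' or 'm'")
    X, names = _build_design(
        dataset, proportions, drop_cell_type, use_raw_proportions, include_age
    )
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need more samples ({n}) than design columns ({p})")
    Y = dataset.betas.to_numpy(dtype=float)
    if scale == "m":
        Y = beta_to_m(np.clip(Y, 0.001, 0.999))
    g = names.index("group_neg")

    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # p x probes
    resid = Y - X @ B
    df = n - p
    s2 = (resid**2).sum(axis=0) / df
    c_gg = XtX_inv[g, g]
    stdev_unscaled = np.sqrt(c_gg)

    beta_hat = B[g]
    degenerate = (np.ptp(Y, axis=0) == 0) | (s2 <= 0)
    s = np.sqrt(np.where(degenerate, np.nan, s2))
    se = s * stdev_unscaled
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta_hat / se
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)

    table = pd.DataFrame(
        {
            "beta_hat": beta_hat,
            "se": se,
            "sigma": s,
            "t": t,
            "df": float(df),
            "p_raw": p_raw,
            "degenerate": degenerate,
        },
        index=dataset.betas.columns,
    )
    if degenerate.any():
        logger.warning(
            "%d zero-variance probes flagged degenerate and excluded from inference",
            int(degenerate.sum()),
        )
    return DmpResult(
        table=table,
        scale=scale,
        stdev_unscaled=pd.Series(stdev_unscaled, index=table.index),
    )


# -- empirical-Bayes variance moderation ----------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior (d0, s0^2)
    to observed residual variances, using moments of log variances.

    Returns (d0, s0sq); d0 = inf means complete shrinkage (all variances
    compatible with a single pooled value).
    """
    s2 = np.asarray(s2, float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need at least 2 positive variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0sq = np.exp(emean)
    return float(d0), float(s0sq)


def moderate_variances(result: DmpResult, prior: tuple | None = None) -> DmpResult:
    """Shrink per-probe variances toward the fitted prior; moderated t.

    The posterior variance is s_tilde^2 = (d0 s0^2 + df s^2) / (d0 + df);
    the moderated t is beta_hat / (stdev_unscaled * s_tilde) on df + d0
    degrees of freedom.  ``prior=(d0, s0sq)`` overrides the moment fit
    (useful to study the no-shrinkage d0=0 and complete-shrinkage d0=inf
    limits).  Falls back to the ordinary t (with a warning) if the moment
    fit is not finite.
    """
    table = result.table.copy()
    valid = ~table["degenerate"].to_numpy()
    s2 = table.loc[valid, "sigma"].to_numpy() ** 2
    df = float(table["df"].iloc[0])
    if prior is None and valid.sum() < 10:
        raise ValueError("need >= 10 probes with valid residual variances")
    try:
        d0, s0sq = fit_variance_prior(s2, df) if prior is None else map(float, prior)
        if not np.isfinite(s0sq) or s0sq <= 0:
            raise ValueError("non-finite prior variance")
    except ValueError as exc:
        logger.warning("variance prior fit failed (%s); using ordinary t", exc)
        table["t_moderated"] = table["t"]
        table["df_moderated"] = table["df"]
        table["p_moderated"] = table["p_raw"]
        return dataclasses.replace(result, table=table)

    s2_all = table["sigma"].to_numpy() ** 2
    if np.isinf(d0):
        s2_post = np.full_like(s2_all, s0sq)
        df_mod = np.inf
    else:
        s2_post = (d0 * s0sq + df * s2_all) / (d0 + df)
        df_mod = df + d0
    stdev = result.stdev_unscaled.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = table["beta_hat"].to_numpy() / (stdev * np.sqrt(s2_post))
    if np.isinf(df_mod):
        p_mod = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_mod)
    t_mod = np.where(valid, t_mod, np.nan)
    p_mod = np.where(valid, p_mod, np.nan)
    table["t_moderated"] = t_mod
    table["df_moderated"] = df_mod
    table["p_moderated"] = p_mod
    return dataclasses.replace(result, table=table, prior_df=d0, prior_var=s0sq)


# -- empirical-null inflation correction ----------------------------------

def t_to_z(t: np.ndarray, df) -> np.ndarray:
    """Map t statistics to signed standard-normal z via their p-values."""
    t = np.asarray(t, float)
    if np.isinf(df):
        return t.copy()
    p_half = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(p_half, 1e-300, 1.0))
    return np.sign(t) * z


def _em_empirical_null(
    z: np.ndarray, max_iter: int = 200, tol: float = 1e-6
) -> tuple[float, float, float, float, float, bool]:
    """Three-component Gaussian mixture EM with symmetric tail components.

    Null: N(mu0, sigma0^2); tails: N(mu0 -/+ mu1, sigma1^2) with separate
    weights.  Identifiability constraints keep the tail components from
    absorbing the shoulders of a pure-null input: tail means sit at least
    two null-SDs from the null center (non-null effects are displaced from
    the bulk by definition) and the tail spread is at least the null spread.
    """
    mu0 = float(np.median(z))
    sigma0 = float(1.4826 * np.median(np.abs(z - mu0))) or float(np.std(z)) or 1.0
    mu1 = 2.0 * sigma0
    sigma1 = sigma0
    w = np.array([0.90, 0.05, 0.05])
    loglik_old = -np.inf
    converged = False
    for _ in range(max_iter):
        means = np.array([mu0, mu0 - mu1, mu0 + mu1])
        sds = np.array([sigma0, sigma1, sigma1])
        dens = w[None, :] * stats.norm.pdf(z[:, None], means[None, :], sds[None, :])
        total = dens.sum(axis=1)
        total = np.where(total <= 0, 1e-300, total)
        loglik = float(np.log(total).sum())
        r = dens / total[:, None]
        nk = r.sum(axis=0)
        w = nk / nk.sum()
        # null component
        mu0 = float((r[:, 0] * z).sum() / max(nk[0], 1e-12))
        sigma0 = float(
            np.sqrt((r[:, 0] * (z - mu0) ** 2).sum() / max(nk[0], 1e-12))
        )
        sigma0 = max(sigma0, 1e-3)
        # symmetric tails around mu0
        num = (r[:, 2] * (z - mu0)).sum() - (r[:, 1] * (z - mu0)).sum()
        mu1 = float(num / max(nk[1] + nk[2], 1e-12))
        mu1 = max(mu1, 2.0 * sigma0)
        var1 = (
            (r[:, 1] * (z - (mu0 - mu1)) ** 2).sum()
            + (r[:, 2] * (z - (mu0 + mu1)) ** 2).sum()
        ) / max(nk[1] + nk[2], 1e-12)
        sigma1 = float(max(np.sqrt(max(var1, 1e-6)), sigma0))
        if abs(loglik - loglik_old) < tol * (1.0 + abs(loglik)):
            converged = True
            break
        loglik_old = loglik
    return mu0, sigma0, float(w[0]), mu1, sigma1, converged


def correct_inflation(
    z_scores: np.ndarray, min_n: int = 1000
) -> tuple[InflationFit, np.ndarray]:
    """Estimate the empirical null of the z-scores and rescale them.

    Returns the fit and the corrected two-sided p-values.  With fewer than
    ``min_n`` finite z-scores the fit is unstable, so an identity
    correction (mu0=0, sigma0=1) is applied with a warning.
    """
    z = np.asarray(z_scores, float)
    finite = np.isfinite(z)
    zf = z[finite]
    lambda_gc = float(np.median(zf**2) / CHI2_MEDIAN) if zf.size else np.nan

    if zf.size < min_n:
        logger.warning(
            "only %d z-scores (<%d); applying identity inflation correction",
            zf.size,
            min_n,
        )
        fit = InflationFit(0.0, 1.0, 1.0, np.nan, np.nan, lambda_gc, False, "identity")
        p = np.full_like(z, np.nan)
        p[finite] = 2.0 * stats.norm.sf(np.abs(zf))
        return fit, p

    mu0, sigma0, pi0, mu1, sigma1, converged = _em_empirical_null(zf)
    method = "em"
    if not converged:
        logger.warning("empirical-null EM did not converge; using median/MAD null")
        mu0 = float(np.median(zf))
        sigma0 = float(1.4826 * np.median(np.abs(zf - mu0)))
        pi0, mu1, sigma1 = 1.0, np.nan, np.nan
        method = "median_mad"
    fit = InflationFit(mu0, sigma0, pi0, mu1, sigma1, lambda_gc, converged, method)
    p = np.full_like(z, np.nan)
    zc = (zf - mu0) / sigma0
    p[finite] = 2.0 * stats.norm.sf(np.abs(zc))
    return fit, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs passed through)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# -- full pipeline ---------------------------------------------------------

def dmp_pipeline(
    dataset: MethylationDataset,
    proportions: CellProportions | None = None,
    scale: str = "beta",
) -> tuple[DmpResult, InflationFit]:
    """Fit, moderate, inflation-correct, and FDR-adjust, genome-wide.

    The q column is BH over the inflation-corrected p-values of all probes
    (tier analyses re-apply BH within each tier's probe set).
    """
    result = fit_dmp(dataset, proportions, scale=scale)
    result = moderate_variances(result)
    table = result.table
    z = t_to_z(table["t_moderated"].to_numpy(), table["df_moderated"].iloc[0])
    fit, p_corr = correct_inflation(z)
    table["z"] = z
    table["p_corrected"] = p_corr
    table["q"] = bh_fdr(p_corr)
    return dataclasses.replace(result, table=table), fit
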