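"""Probe exclusion, beta/M transforms, and PCA-based QC summaries.

Probe filtering mirrors standard EPIC-array practice: drop probes flagged
as cross-reactive, and drop probes with a known SNP of minor-allele
frequency strictly above a threshold (default 0.01) in the CpG dinucleotide
itself, at the single-base-extension position, or in the probe body.
Missing MAF annotation is treated as "no known SNP".  Sex-chromosome probes
are retained by default (appropriate for a single-sex cohort); pass
``drop_sex=True`` to remove chrX/chrY probes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datasets import MethylationDataset

logger = logging.getLogger(__name__)

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclasses.dataclass
class FilterReport:
    n_input: int
    n_removed_cross_reactive: int
    n_removed_snp: int
    n_removed_sex: int
    n_retained: int
    removed_ids: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_input",
                    "n_removed_cross_reactive",
                    "n_removed_snp",
                    "n_removed_sex",
                    "n_retained",
                ],
                "value": [
                    self.n_input,
                    self.n_removed_cross_reactive,
                    self.n_removed_snp,
                    self.n_removed_sex,
                    self.n_retained,
                ],
            }
        )


def filter_probes(
    dataset: MethylationDataset,
    maf_threshold: float = 0.01,
    drop_sex: bool = False,
) -> tuple[MethylationDataset, FilterReport]:
    """Exclude cross-reactive and SNP-affected probes.

    A probe is counted once, under the first matching rule (cross-reactive
    before SNP before sex); probe order is otherwise preserved.  The MAF
    rule is a strict inequality: a probe at exactly the threshold is kept.
    Idempotent: filtering an already-filtered dataset changes nothing.
    """
    ann = dataset.probes
    cross = ann["cross_reactive"].fillna(0).astype(int).to_numpy() != 0
    maf = ann[["maf_cpg", "maf_sbe", "maf_body"]].to_numpy(dtype=float)
    n_missing_maf = int(np.isnan(maf).all(axis=1).sum())
    if n_missing_maf:
        logger.info(
            "%d probes lack all MAF annotation; treated as not exceeding threshold",
            n_missing_maf,
        )
    with np.errstate(invalid="ignore"):
        snp = np.nansum(maf > maf_threshold, axis=1) > 0
    sex = ann["chrom"].isin(SEX_CHROMS).to_numpy() if drop_sex else np.zeros(len(ann), bool)

    removed_cross = cross
    removed_snp = snp & ~cross
    removed_sex = sex & ~cross & ~snp
    keep = ~(cross | snp | sex)

    retained_ids = list(ann.index[keep])
    report = FilterReport(
        n_input=len(ann),
        n_removed_cross_reactive=int(removed_cross.sum()),
        n_removed_snp=int(removed_snp.sum()),
        n_removed_sex=int(removed_sex.sum()),
        n_retained=len(retained_ids),
        removed_ids=list(ann.index[~keep]),
    )
    return dataset.subset_probes(retained_ids), report


def beta_to_m(beta):
    """M-value transform, m = log2(beta / (1 - beta)).

    Expects betas already clipped away from {0, 1} (the generator and
    loaders enforce [0.001, 0.999]).
    """
    beta = np.asarray(beta, dtype=float)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + 2.0**-m)


def pca_summary(dataset: MethylationDataset, k: int = 8) -> dict:
    """Principal components of the probe-centered beta matrix.

    Returns the first ``k`` explained-variance fractions (relative to total
    variance, so the full spectrum sums to 1), the sample scores, and —
    handy for QC — the Pearson correlation of each score vector with group
    membership and age.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    k = min(k, dataset.n_samples - 1, dataset.n_probes)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(dataset.betas.to_numpy())
    fractions = pca.explained_variance_ratio_

    covars = pd.DataFrame(
        {
            "group_neg": dataset.group_mask_neg.astype(float),
            "age": dataset.samples["age"].to_numpy(dtype=float),
        }
    )
    corr = {}
    for name, v in covars.items():
        vv = v.to_numpy()
        if np.std(vv) == 0:
            corr[name] = np.full(k, np.nan)
        else:
            corr[name] = np.array(
                [np.corrcoef(scores[:, i], vv)[0, 1] for i in range(k)]
            )
    return {
        "explained_variance_fraction": fractions,
        "scores": pd.DataFrame(
            scores,
            index=dataset.betas.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        "covariate_correlation": pd.DataFrame(corr, index=[f"PC{i + 1}" for i in range(k)]),
    }
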