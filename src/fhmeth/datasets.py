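"""Core containers and tabular IO for methylation-array cohorts.

The central object is :class:`MethylationDataset`: a samples x probes matrix of
beta values (methylated fraction, in [0, 1]) together with a sample sheet
(group label, age) and a manifest-like probe annotation table.  Everything
downstream — probe filtering, cell deconvolution, per-CpG regression, the
machine-learning discriminator — transforms this object.

All artifacts serialize to plain TSV.  Coordinates are 1-based and intervals
are both-ends inclusive, matching array-manifest convention (hg19-style).
Group labels are fixed to ``{"neg", "pos"}``: ``neg`` = FH mutation-negative
(no pathogenic LDLR/APOB/PCSK9 variant found), ``pos`` = mutation-positive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_LABELS = ("neg", "pos")

#: sample sheet columns
SAMPLE_COLUMNS = ["sample_id", "group", "age"]
#: probe annotation columns; maf_* may be NaN (missing)
ANNOTATION_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "gene",
    "gene_feature",
    "cross_reactive",
    "maf_cpg",
    "maf_sbe",
    "maf_body",
]


class DatasetError(ValueError):
    """Raised when a dataset's components are inconsistent or out of range."""


@dataclasses.dataclass
class MethylationDataset:
    """Beta matrix plus sample metadata and probe annotation.

    Parameters
    ----------
    betas
        ``(n_samples, n_probes)`` DataFrame, index = sample ids,
        columns = probe ids, values in [0, 1].
    samples
        DataFrame with columns ``sample_id, group, age`` (group in
        {"neg", "pos"}, age in years), indexed by ``sample_id``.
    probes
        DataFrame with the :data:`ANNOTATION_COLUMNS`, indexed by
        ``probe_id``.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- consistency -------------------------------------------------------
    def validate(self) -> None:
        if self.betas.index.duplicated().any():
            dupes = self.betas.index[self.betas.index.duplicated()].tolist()
            raise DatasetError(f"duplicate sample ids: {dupes}")
        if self.betas.columns.duplicated().any():
            dupes = self.betas.columns[self.betas.columns.duplicated()].tolist()
            raise DatasetError(f"duplicate probe ids: {dupes}")
        if list(self.betas.index) != list(self.samples.index):
            missing = set(self.betas.index) ^ set(self.samples.index)
            raise DatasetError(
                f"sample sheet and beta matrix disagree on samples: {sorted(missing)}"
            )
        if list(self.betas.columns) != list(self.probes.index):
            missing = set(self.betas.columns) ^ set(self.probes.index)
            raise DatasetError(
                f"annotation and beta matrix disagree on probes: {sorted(missing)}"
            )
        values = self.betas.to_numpy()
        if not np.isfinite(values).all():
            raise DatasetError("beta matrix contains non-finite values")
        bad = np.argwhere((values < 0.0) | (values > 1.0))
        if bad.size:
            i, j = bad[0]
            raise DatasetError(
                f"beta value out of [0, 1]: {values[i, j]:g} at "
                f"sample {self.betas.index[i]!r}, probe {self.betas.columns[j]!r}"
            )
        unknown = set(self.samples["group"]) - set(GROUP_LABELS)
        if unknown:
            raise DatasetError(f"unknown group labels: {sorted(unknown)}")
        if (self.probes["pos"] < 1).any():
            raise DatasetError("probe positions must be >= 1 (1-based)")
        for col in ("maf_cpg", "maf_sbe", "maf_body"):
            vals = self.probes[col].dropna()
            if ((vals < 0) | (vals > 0.5)).any():
                raise DatasetError(f"{col} outside [0, 0.5]")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.betas.shape[0]

    @property
    def n_probes(self) -> int:
        return self.betas.shape[1]

    @property
    def group_mask_neg(self) -> np.ndarray:
        """Boolean mask over samples, True = FH mutation-negative."""
        return (self.samples["group"] == "neg").to_numpy()

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        """Dataset restricted to ``probe_ids`` (order as given)."""
        probe_ids = list(probe_ids)
        return MethylationDataset(
            betas=self.betas.loc[:, probe_ids].copy(),
            samples=self.samples.copy(),
            probes=self.probes.loc[probe_ids].copy(),
        )

    # -- IO ----------------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        """Write betas/sample sheet/annotation as TSV under ``outdir``.

        The beta matrix is written probes x samples (probe id as row key),
        the orientation array pipelines conventionally exchange.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.betas.T.to_csv(outdir / "betas.tsv", sep="\t", index_label="probe_id")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.probes.to_csv(outdir / "annotation.tsv", sep="\t", index=False)


def load_dataset(indir: str | Path) -> MethylationDataset:
    """Load a dataset written by :meth:`MethylationDataset.write`.

    Raises
    ------
    DatasetError
        On shape mismatch, duplicate ids, non-numeric cells, or beta values
        outside [0, 1]; the message names the offending probe/sample.
    """
    indir = Path(indir)
    for name in ("betas.tsv", "samples.tsv", "annotation.tsv"):
        if not (indir / name).exists():
            raise DatasetError(f"missing dataset file: {indir / name}")
    raw = pd.read_csv(indir / "betas.tsv", sep="\t", index_col="probe_id")
    try:
        betas = raw.astype(float).T
    except ValueError as exc:
        raise DatasetError(f"non-numeric cell in beta matrix: {exc}") from exc
    samples = pd.read_csv(indir / "samples.tsv", sep="\t")
    missing_cols = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing_cols:
        raise DatasetError(f"sample sheet missing columns: {sorted(missing_cols)}")
    samples = samples.set_index("sample_id", drop=False)
    samples.index.name = None
    probes = pd.read_csv(indir / "annotation.tsv", sep="\t", keep_default_na=True)
    missing_cols = set(ANNOTATION_COLUMNS) - set(probes.columns)
    if missing_cols:
        raise DatasetError(f"annotation missing columns: {sorted(missing_cols)}")
    probes["gene"] = probes["gene"].fillna("")
    probes = probes.set_index("probe_id", drop=False)
    probes.index.name = None
    # align metadata row order to the matrix before the consistency check,
    # but only for ids present on both sides
    common_samples = [s for s in betas.index if s in samples.index]
    common_probes = [p for p in betas.columns if p in probes.index]
    if len(common_samples) == len(betas.index) == len(samples):
        samples = samples.loc[betas.index]
    if len(common_probes) == len(betas.columns) == len(probes):
        probes = probes.loc[betas.columns]
    return MethylationDataset(betas=betas, samples=samples, probes=probes)


def make_annotation(
    probe_ids,
    chrom,
    pos,
    gene=None,
    gene_feature=None,
    cross_reactive=None,
    maf_cpg=None,
    maf_sbe=None,
    maf_body=None,
) -> pd.DataFrame:
    """Assemble a probe annotation frame with defaults for optional fields."""
    n = len(probe_ids)
    frame = pd.DataFrame(
        {
            "probe_id": list(probe_ids),
            "chrom": list(chrom),
            "pos": np.asarray(pos, dtype=np.int64),
            "gene": [""] * n if gene is None else list(gene),
            "gene_feature": [""] * n if gene_feature is None else list(gene_feature),
            "cross_reactive": np.zeros(n, dtype=int)
            if cross_reactive is None
            else np.asarray(cross_reactive, dtype=int),
            "maf_cpg": np.full(n, np.nan) if maf_cpg is None else np.asarray(maf_cpg, float),
            "maf_sbe": np.full(n, np.nan) if maf_sbe is None else np.asarray(maf_sbe, float),
            "maf_body": np.full(n, np.nan) if maf_body is None else np.asarray(maf_body, float),
        }
    )
    frame = frame.set_index("probe_id", drop=False)
    frame.index.name = None
    return frame
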