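"""The published top-20 discriminating CpG table and summaries over it.

The packaged fixture is the study's top-20 CpG sites ranked by relative
feature importance in the gradient-boosting model that separates FH
mutation-negative from mutation-positive patients (hg19 coordinates).
Direction is relative to the mutation-negative group: ``hyper`` means the
median normalized beta is higher in mutation-negative samples.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import pandas as pd

DIRECTIONS = ("hyper", "hypo")


@dataclasses.dataclass(frozen=True)
class TopFeatureSummary:
    pct_hyper: float
    n_hypo: int
    n_without_gene: int
    max_importance: float


def load_top_feature_fixture() -> pd.DataFrame:
    """Load the packaged top-20 feature table.

    Returns a DataFrame with columns rank, probe_id, gene (empty string for
    intergenic probes without a nearby gene), chrom, pos, gene_feature,
    direction (hyper/hypo) and relative_importance (0-100, max exactly 100).
    """
    ref = resources.files("fhmeth").joinpath("data/top20_features.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", keep_default_na=False)
    table["relative_importance"] = table["relative_importance"].astype(float)
    table["pos"] = table["pos"].astype(int)
    return table


def summarize_top_features(table: pd.DataFrame) -> TopFeatureSummary:
    """Headline counts over a top-feature table.

    ``pct_hyper`` is 100 * (rows with direction hyper) / rows;
    ``n_without_gene`` counts rows with an empty gene symbol.
    """
    if len(table) == 0:
        raise ValueError("empty top-feature table")
    unknown = set(table["direction"]) - set(DIRECTIONS)
    if unknown:
        raise ValueError(f"unknown direction values: {sorted(unknown)}")
    n = len(table)
    n_hyper = int((table["direction"] == "hyper").sum())
    gene = table["gene"].fillna("").astype(str).str.strip()
    return TopFeatureSummary(
        pct_hyper=100.0 * n_hyper / n,
        n_hypo=n - n_hyper,
        n_without_gene=int((gene == "").sum()),
        max_importance=float(table["relative_importance"].max()),
    )
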