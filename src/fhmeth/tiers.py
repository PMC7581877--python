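"""Tiered candidate-gene analysis.

Candidate CpGs are organised in four tiers of decreasing prior evidence:

* tier 1 — the major FH genes (LDLR, APOB, PCSK9);
* tier 2 — the minor FH genes (LDLRAP, STAP1, ABCG5, ABCG8, APOE, LIPA);
* tier 3 — genes associated with LDL-C / total cholesterol in large GWAS
  (configurable; content is data, not algorithm);
* tier 4 — individual CpG ids with published lipid associations
  (configurable; defaults to the CPT1A CpG cg00574958).

For gene tiers, every probe within ``flank_bp`` (default 3000) base pairs
of the gene interval, on either side, is analysed — covering promoter and
nearby regulatory CpGs the manifest does not annotate to the gene.  Tier
statistics are row-subsets of a single genome-wide fit (no per-tier
refitting); BH-FDR is applied within each tier's probe set by default.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import yaml

from .datasets import MethylationDataset
from .deconv import CellProportions
from .dmp import DmpResult, InflationFit, bh_fdr, dmp_pipeline

logger = logging.getLogger(__name__)

TIER1_GENES = ("LDLR", "APOB", "PCSK9")
TIER2_GENES = ("LDLRAP", "STAP1", "ABCG5", "ABCG8", "APOE", "LIPA")
DEFAULT_TIER4_CPGS = ("cg00574958",)
DEFAULT_FLANK_BP = 3000

TIER_LABELS = ("tier1", "tier2", "tier3", "tier4")


@dataclasses.dataclass
class TierRegistry:
    """The four candidate tiers plus gene coordinate intervals.

    ``gene_intervals`` maps gene symbol -> (chrom, start, end), 1-based and
    both-ends inclusive.
    """

    tier3_genes: tuple = ()
    tier4_cpgs: tuple = DEFAULT_TIER4_CPGS
    gene_intervals: dict = dataclasses.field(default_factory=dict)
    tier1_genes: tuple = TIER1_GENES
    tier2_genes: tuple = TIER2_GENES

    def __post_init__(self):
        for gene, (chrom, start, end) in self.gene_intervals.items():
            if start > end or start < 1:
                raise ValueError(f"malformed interval for {gene}: {(chrom, start, end)}")

    def genes_for(self, tier: str) -> tuple:
        return {
            "tier1": self.tier1_genes,
            "tier2": self.tier2_genes,
            "tier3": self.tier3_genes,
        }[tier]

    @classmethod
    def from_yaml(cls, path) -> "TierRegistry":
        """Load tier-3 genes, tier-4 CpGs and gene intervals from YAML.

        Schema::

            tier3_genes: [SORT1, ...]
            tier4_cpgs: [cg00574958, ...]
            gene_intervals:
              LDLR: {chrom: chr19, start: 11200000, end: 11244000}
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        intervals = {
            g: (v["chrom"], int(v["start"]), int(v["end"]))
            for g, v in (raw.get("gene_intervals") or {}).items()
        }
        return cls(
            tier3_genes=tuple(raw.get("tier3_genes") or ()),
            tier4_cpgs=tuple(raw.get("tier4_cpgs") or DEFAULT_TIER4_CPGS),
            gene_intervals=intervals,
        )


def registry_from_annotation(
    annotation: pd.DataFrame,
    tier3_genes=(),
    tier4_cpgs=DEFAULT_TIER4_CPGS,
) -> TierRegistry:
    """Build a registry whose gene intervals span each gene's annotated probes.

    Convenient for synthetic manifests, where the probe layout defines the
    gene span.
    """
    intervals = {}
    genes = annotation["gene"].fillna("")
    for gene in sorted(set(genes) - {""}):
        sub = annotation[genes == gene]
        chrom = sub["chrom"].iloc[0]
        intervals[gene] = (chrom, int(sub["pos"].min()), int(sub["pos"].max()))
    return TierRegistry(
        tier3_genes=tuple(tier3_genes),
        tier4_cpgs=tuple(tier4_cpgs),
        gene_intervals=intervals,
    )


def select_tier_probes(
    annotation: pd.DataFrame,
    registry: TierRegistry,
    tier: str,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list:
    """Probe ids belonging to a tier.

    Gene tiers take every probe with matching chromosome and position in
    [start - flank, end + flank], both endpoints inclusive (start - flank
    clamped at 1); tier 4 is an exact CpG-id match.  Selection is
    deterministic: ids are returned in annotation order, each at most once.
    """
    if tier not in TIER_LABELS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIER_LABELS}")
    if tier == "tier4":
        wanted = set(registry.tier4_cpgs)
        found = [p for p in annotation.index if p in wanted]
        missing = wanted - set(found)
        if missing:
            logger.warning("tier4 CpGs absent from annotation: %s", sorted(missing))
        return found
    selected = pd.Series(False, index=annotation.index)
    for gene in registry.genes_for(tier):
        if gene not in registry.gene_intervals:
            logger.warning("no interval for %s gene %r; skipped", tier, gene)
            continue
        chrom, start, end = registry.gene_intervals[gene]
        lo = max(1, start - flank_bp)
        hi = end + flank_bp
        hit = (
            (annotation["chrom"] == chrom)
            & (annotation["pos"] >= lo)
            & (annotation["pos"] <= hi)
        )
        selected |= hit
    return list(annotation.index[selected])


def run_candidate_analysis(
    dataset: MethylationDataset,
    proportions: CellProportions | None,
    registry: TierRegistry,
    flank_bp: int = DEFAULT_FLANK_BP,
    fdr_scope: str = "tier",
    scale: str = "beta",
) -> tuple[dict, DmpResult, InflationFit]:
    """Genome-wide fit, then per-tier tables.

    Each tier's table is a row-subset of the genome-wide moderated,
    inflation-corrected results, with BH-FDR recomputed within the tier
    (``fdr_scope='tier'``, the default) or taken from the genome-wide
    adjustment (``fdr_scope='genome'``); tables are sorted by q.
    """
    if fdr_scope not in ("tier", "genome"):
        raise ValueError("fdr_scope must be 'tier' or 'genome'")
    genome, inflation = dmp_pipeline(dataset, proportions, scale=scale)
    tier_tables = {}
    for tier in TIER_LABELS:
        probe_ids = select_tier_probes(dataset.probes, registry, tier, flank_bp)
        if not probe_ids:
            logger.warning("%s selected zero probes", tier)
            tier_tables[tier] = genome.table.iloc[0:0].copy()
            continue
        sub = genome.table.loc[probe_ids].copy()
        if fdr_scope == "tier":
            sub["q"] = bh_fdr(sub["p_corrected"].to_numpy())
        tier_tables[tier] = sub.sort_values("q", kind="mergesort")
    return tier_tables, genome, inflation
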