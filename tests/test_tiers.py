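"""Candidate-tier probe selection and the tiered differential analysis."""

import numpy as np
import pandas as pd
import pytest

from fhmeth.datasets import make_annotation
from fhmeth.deconv import estimate_proportions
from fhmeth.synthdata import CohortConfig, SpikeSpec, generate_cohort
from fhmeth.tiers import (
    TIER1_GENES,
    TierRegistry,
    registry_from_annotation,
    run_candidate_analysis,
    select_tier_probes,
)


@pytest.fixture()
def window_annotation():
    """Probes placed around a gene at chr1:100000-105000."""
    return make_annotation(
        ["p_in_low", "p_at_low", "p_at_high", "p_out_high", "p_other_chrom"],
        chrom=["chr1", "chr1", "chr1", "chr1", "chr2"],
        pos=[96999, 97000, 108000, 108001, 100000],
    )


class TestSelection:
    def test_inclusive_window_boundaries(self, window_annotation):
        registry = TierRegistry(
            tier3_genes=("GENEA",),
            gene_intervals={"GENEA": ("chr1", 100000, 105000)},
        )
        got = select_tier_probes(window_annotation, registry, "tier3", flank_bp=3000)
        assert got == ["p_at_low", "p_at_high"]

    def test_tier1_is_major_fh_genes(self, small_cohort):
        dataset, _ = small_cohort
        registry = registry_from_annotation(dataset.probes)
        probes = select_tier_probes(dataset.probes, registry, "tier1")
        assert len(probes) > 0
        genes = set(dataset.probes.loc[probes, "gene"])
        assert genes <= set(TIER1_GENES)
        for g in TIER1_GENES:
            assert g in genes

    def test_tier4_exact_match_once(self, small_cohort):
        dataset, _ = small_cohort
        registry = registry_from_annotation(dataset.probes)
        probes = select_tier_probes(dataset.probes, registry, "tier4")
        assert probes == ["cg00574958"]

    def test_flank_monotonicity(self, small_cohort):
        dataset, _ = small_cohort
        registry = registry_from_annotation(dataset.probes)
        sizes = [
            len(select_tier_probes(dataset.probes, registry, "tier2", flank_bp=f))
            for f in (0, 1000, 3000, 10000)
        ]
        assert sizes == sorted(sizes)

    def test_probe_order_independence(self, small_cohort):
        dataset, _ = small_cohort
        registry = registry_from_annotation(dataset.probes)
        shuffled = dataset.probes.sample(frac=1, random_state=0)
        a = set(select_tier_probes(dataset.probes, registry, "tier1"))
        b = set(select_tier_probes(shuffled, registry, "tier1"))
        assert a == b

    def test_unknown_tier_rejected(self, window_annotation):
        with pytest.raises(ValueError, match="tier9"):
            select_tier_probes(window_annotation, TierRegistry(), "tier9")

    def test_missing_tier4_cpg_warns_and_empties(self, window_annotation, caplog):
        registry = TierRegistry(tier4_cpgs=("cg_not_there",))
        with caplog.at_level("WARNING"):
            got = select_tier_probes(window_annotation, registry, "tier4")
        assert got == []
        assert "cg_not_there" in caplog.text

    def test_registry_from_yaml(self, tmp_path):
        cfg = tmp_path / "tiers.yaml"
        cfg.write_text(
            "tier3_genes: [SORT1, ABCA1]\n"
            "tier4_cpgs: [cg00574958, cg26426080]\n"
            "gene_intervals:\n"
            "  LDLR: {chrom: chr19, start: 11200038, end: 11244506}\n"
        )
        registry = TierRegistry.from_yaml(cfg)
        assert registry.tier1_genes == TIER1_GENES
        assert registry.tier3_genes == ("SORT1", "ABCA1")
        assert registry.tier4_cpgs == ("cg00574958", "cg26426080")
        assert registry.gene_intervals["LDLR"] == ("chr19", 11200038, 11244506)

    def test_window_clamped_at_one(self):
        ann = make_annotation(["p1"], chrom=["chr1"], pos=[5])
        registry = TierRegistry(
            tier3_genes=("G",), gene_intervals={"G": ("chr1", 100, 200)}
        )
        got = select_tier_probes(ann, registry, "tier3", flank_bp=500)
        assert got == ["p1"]


@pytest.fixture(scope="module")
def spiked_run(reference):
    cfg = CohortConfig(n_probes=300, noise_sd_logit=0.05, seed=60)
    ds, _ = generate_cohort(cfg, reference, spikes=[SpikeSpec("cg00574958", -0.013)])
    props = estimate_proportions(ds, reference)
    registry = registry_from_annotation(ds.probes, tier3_genes=("SORT1", "ABCA1"))
    tables, genome, inflation = run_candidate_analysis(ds, props, registry)
    return ds, tables, genome


class TestCandidateAnalysis:

    def test_single_tier4_hit_mirrors_candidate_result(self, spiked_run, reference):
        """A planted CPT1A-like effect surfaces in tier 4; the other tiers
        stay at chance level (zero discoveries in most replicates)."""
        _, tables, _ = spiked_run
        t4 = tables["tier4"]
        assert (t4["q"] < 0.05).sum() == 1
        assert t4.index[0] == "cg00574958"
        assert t4.loc["cg00574958", "beta_hat"] < 0
        clean_replicates = 0
        for seed in (60, 61, 62):
            cfg = CohortConfig(n_probes=300, noise_sd_logit=0.05, seed=seed)
            ds, _ = generate_cohort(
                cfg, reference, spikes=[SpikeSpec("cg00574958", -0.013)]
            )
            props = estimate_proportions(ds, reference)
            registry = registry_from_annotation(ds.probes)
            reps, _, _ = run_candidate_analysis(ds, props, registry)
            assert reps["tier4"].loc["cg00574958", "q"] < 0.05
            if all((reps[t]["q"] >= 0.05).all() for t in ("tier1", "tier2", "tier3")):
                clean_replicates += 1
        assert clean_replicates >= 2

    def test_tier_tables_are_subsets_of_genome_fit(self, spiked_run):
        _, tables, genome = spiked_run
        for tier, sub in tables.items():
            assert set(sub.index) <= set(genome.table.index)
            np.testing.assert_allclose(
                sub["t_moderated"].to_numpy(),
                genome.table.loc[sub.index, "t_moderated"].to_numpy(),
            )

    def test_null_tiers_have_no_discoveries(self, reference):
        """No spikes: across replicates the tiers stay empty at q < 0.05."""
        hits = 0
        for seed in (70, 71, 72):
            cfg = CohortConfig(n_probes=300, seed=seed)
            ds, _ = generate_cohort(cfg, reference)
            props = estimate_proportions(ds, reference)
            registry = registry_from_annotation(ds.probes)
            tables, _, _ = run_candidate_analysis(ds, props, registry)
            hits += sum((t["q"] < 0.05).sum() for t in tables.values())
        assert hits <= 1

    def test_empty_tier_returns_empty_table(self, small_cohort, reference, caplog):
        ds, _ = small_cohort
        props = estimate_proportions(ds, reference)
        registry = registry_from_annotation(ds.probes, tier4_cpgs=("cg_missing",))
        with caplog.at_level("WARNING"):
            tables, _, _ = run_candidate_analysis(ds, props, registry)
        assert len(tables["tier4"]) == 0

    def test_genome_fdr_scope(self, spiked_run, reference):
        ds, _, genome = spiked_run
        props = estimate_proportions(ds, reference)
        registry = registry_from_annotation(ds.probes)
        tables, genome2, _ = run_candidate_analysis(
            ds, props, registry, fdr_scope="genome"
        )
        np.testing.assert_allclose(
            tables["tier4"]["q"].to_numpy(),
            genome2.table.loc[tables["tier4"].index, "q"].to_numpy(),
        )
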