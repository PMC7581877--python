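#!/usr/bin/env python
"""Simulate the study cohort: 78 FH mutation-negative vs 58 mutation-positive
male patients, 2000 CpG probes, six-leukocyte-type blood mixtures.

Plants the candidate-gene analysis' known effect (the CPT1A CpG cg00574958,
1.3 percentage points lower methylation in mutation-negative patients), one
SNP-artifact probe with trimodal methylation, and flags a handful of filler
probes as cross-reactive / SNP-affected so the QC step has work to do.
Writes the dataset (betas, sample sheet, annotation), the hidden truth, and
a summary of what was planted.
"""

import argparse
from pathlib import Path

import numpy as np

from fhmeth.synthdata import (
    CohortConfig,
    SnpArtifactSpec,
    SpikeSpec,
    generate_cell_reference,
    generate_cohort,
    mid_range_filler_probes,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    parser.add_argument("--n-probes", type=int, default=2000)
    args = parser.parse_args()

    rng = np.random.default_rng(args.seed)
    reference = generate_cell_reference(seed=int(rng.integers(2**31)))
    config = CohortConfig(n_probes=args.n_probes, seed=int(rng.integers(2**31)))

    base, _ = generate_cohort(config, reference)
    snp_probe = mid_range_filler_probes(base, 1)[0]
    dataset, truth = generate_cohort(
        config,
        reference,
        spikes=[SpikeSpec("cg00574958", -0.013)],
        snp_artifacts=[
            SnpArtifactSpec(snp_probe, maf=0.3, level_betas=(0.15, 0.5, 0.85))
        ],
    )

    # flag some filler probes for the QC step: 20 cross-reactive, 20 with a
    # common SNP at the CpG / single-base-extension / probe-body position
    fillers = [p for p in dataset.betas.columns if p.startswith("cg5")]
    dataset.probes.loc[fillers[:20], "cross_reactive"] = 1
    dataset.probes.loc[fillers[20:30], "maf_cpg"] = 0.1
    dataset.probes.loc[fillers[30:35], "maf_sbe"] = 0.05
    dataset.probes.loc[fillers[35:40], "maf_body"] = 0.2

    args.out.mkdir(parents=True, exist_ok=True)
    dataset.write(args.out)
    truth.write(args.out)
    reference.profiles.to_csv(args.out / "cell_reference.tsv", sep="\t")

    print(f"cohort: {dataset.n_samples} samples x {dataset.n_probes} probes")
    print(f"  groups: 78 neg / 58 pos; ages {dataset.samples['age'].min():.0f}-"
          f"{dataset.samples['age'].max():.0f}")
    print(f"  planted: cg00574958 (CPT1A) delta_beta=-0.013; SNP artifact at {snp_probe}")
    print(f"  flagged for QC: 20 cross-reactive, 20 SNP-affected probes")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
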