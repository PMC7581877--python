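#!/usr/bin/env python
"""Correlation-based validation of candidate CpGs.

Stands in for database lookups of methylation-expression correlation:
simulates an expression value for CPT1A that is negatively coupled to
methylation at cg00574958 (promoter-like behavior) plus a triglyceride
phenotype, computes Pearson and Spearman correlations, and applies the
suggestive-relevance rule (p < 0.05 and |r| > 0.1).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fhmeth.assoc import correlate_probes, filter_biological
from fhmeth.datasets import load_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--qc", type=Path, default=Path("results/qc/filtered"))
    parser.add_argument("--out", type=Path, default=Path("results/validation"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument(
        "--expression", type=Path,
        help="optional sample-by-variable TSV to correlate instead of simulating",
    )
    args = parser.parse_args()

    dataset = load_dataset(args.qc)
    probes = ["cg00574958"]
    betas = dataset.betas[probes]

    if args.expression:
        variables = pd.read_csv(args.expression, sep="\t", index_col=0)
    else:
        rng = np.random.default_rng(args.seed)
        m = betas["cg00574958"].to_numpy()
        z = (m - m.mean()) / m.std()
        variables = pd.DataFrame(
            {
                # methylation of this CpG suppresses expression (negative coupling)
                "CPT1A_expression": -0.5 * z + rng.normal(0, 1, len(z)),
                # weak negative coupling to the triglyceride phenotype
                "triglycerides_mmol_l": np.clip(
                    1.6 - 0.15 * z + rng.normal(0, 0.5, len(z)), 0.3, None
                ),
            },
            index=betas.index,
        )

    out = correlate_probes(betas, variables)
    out = filter_biological(out)

    args.out.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out / "correlations.tsv", sep="\t", index=False)

    for _, row in out.iterrows():
        flag = "suggestive" if row["biologically_relevant"] else "not suggestive"
        print(f"{row['probe_id']} vs {row['variable']} [{row['method']}]: "
              f"r={row['r']:+.3f} p={row['p']:.3g} n={row['n']} -> {flag}")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
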