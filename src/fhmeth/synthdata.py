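"""Synthetic methylation-cohort generation.

Emulates the statistical structure of a two-group blood-methylation study:
two groups of patients (FH mutation-negative, n=78, mean age 50.7 +/- 12.3;
FH mutation-positive, n=58, mean age 38.1 +/- 12.0), beta values driven by a
six-leukocyte-type mixture (CD8T, CD4T, NK, B cells, monocytes,
granulocytes) with per-sample proportions drawn from a Dirichlet, optional
spiked group effects on chosen CpGs, optional age trends, and SNP-artifact
probes with trimodal (genotype-driven) methylation levels.

The generative model per probe j and sample i is

    mu_ij  = sum_t w_it * P_jt  (+ delta_beta for spiked probes in the
                                 mutation-negative group)
                                (+ age_slope * (age_i - mean age))
    beta_ij = expit(logit(mu_ij) + eps),  eps ~ N(0, noise_sd_logit)

clipped to [0.001, 0.999]: w_i are the sample's true cell proportions and
P is a probes x cell-types profile matrix.  Noise lives on the logit scale
so that draws respect the [0, 1] beta range, as is standard for array data.
The hidden truth (cell proportions, ages, spikes, genotypes) is returned
alongside the dataset so recovery can be asserted in tests.

A handful of candidate lipid genes (the major/minor FH genes, CPT1A, and a
few GWAS lipid loci) are laid out deterministically in the synthetic
manifest, with hg19-like coordinates, so the tiered candidate-gene analysis
can be exercised end to end; the published CPT1A probe id cg00574958 is
always the first CPT1A probe.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .datasets import MethylationDataset, make_annotation

DEFAULT_CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")
#: Dirichlet concentrations, ordered as DEFAULT_CELL_TYPES; granulocytes
#: dominate whole blood, T cells come next — realistic collinearity for the
#: regression covariates downstream.
DEFAULT_DIRICHLET_ALPHA = (10.0, 10.0, 2.0, 2.0, 2.0, 30.0)

AGE_BOUNDS = (18.0, 90.0)  # adult referral cohort
BETA_CLIP = (0.001, 0.999)

#: deterministic candidate-gene layout for the synthetic manifest:
#: gene -> (chrom, start of its probe block, hg19-like).  Eight probes per
#: gene, spaced 400 bp.
CANDIDATE_GENE_LAYOUT = {
    "LDLR": ("chr19", 11_200_000),
    "APOB": ("chr2", 21_224_000),
    "PCSK9": ("chr1", 55_505_000),
    "LDLRAP": ("chr1", 25_870_000),
    "STAP1": ("chr4", 68_424_000),
    "ABCG5": ("chr2", 44_039_000),
    "ABCG8": ("chr2", 44_066_000),
    "APOE": ("chr19", 45_409_000),
    "LIPA": ("chr10", 90_973_000),
    "CPT1A": ("chr11", 68_522_000),
    "SORT1": ("chr1", 109_852_000),
    "ABCA1": ("chr9", 107_543_000),
    "HMGCR": ("chr5", 74_632_000),
    "CETP": ("chr16", 56_995_000),
    "LPL": ("chr8", 19_796_000),
}
PROBES_PER_GENE = 8
GENE_PROBE_SPACING = 400
#: the published CPT1A CpG associated with LDL-C / total cholesterol
CPT1A_PROBE = "cg00574958"


class SpikeError(ValueError):
    """A spiked effect pushes a probe's mean beta outside [0, 1]."""


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the study conditions: group sizes 78/58, group age
    distributions from the cohort table, six leukocyte types.
    """

    n_group_neg: int = 78
    n_group_pos: int = 58
    age_mean_neg: float = 50.7
    age_sd_neg: float = 12.3
    age_mean_pos: float = 38.1
    age_sd_pos: float = 12.0
    n_probes: int = 1000
    cell_types: tuple = DEFAULT_CELL_TYPES
    dirichlet_alpha: tuple = DEFAULT_DIRICHLET_ALPHA
    noise_sd_logit: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_group_neg <= 0 or self.n_group_pos <= 0 or self.n_probes <= 0:
            raise ValueError("sample and probe counts must be positive")
        if self.noise_sd_logit < 0:
            raise ValueError("noise_sd_logit must be >= 0")
        if len(self.cell_types) != 6:
            raise ValueError("exactly six cell types are required")
        if len(self.dirichlet_alpha) != len(self.cell_types):
            raise ValueError("dirichlet_alpha length must match cell_types")


@dataclasses.dataclass(frozen=True)
class SpikeSpec:
    """A planted group effect at one probe.

    ``delta_beta`` is the mean beta difference, mutation-negative minus
    mutation-positive, on the beta scale (a value of -0.013 plants a
    1.3-percentage-point lower methylation in the mutation-negative group).
    ``age_slope`` is beta units per year, applied to all samples around the
    cohort mean age.
    """

    probe_id: str
    delta_beta: float
    age_slope: float = 0.0

    def __post_init__(self):
        if not -1.0 < self.delta_beta < 1.0:
            raise ValueError("delta_beta must be in (-1, 1)")


@dataclasses.dataclass(frozen=True)
class SnpArtifactSpec:
    """A probe whose signal is dominated by an underlying SNP genotype.

    Samples fall into three methylation levels (one per genotype) with
    Hardy-Weinberg frequencies (1-p)^2, 2p(1-p), p^2 for minor-allele
    frequency p; such probes show the two-or-three-cluster pattern seen on
    real arrays.
    """

    probe_id: str
    maf: float
    level_betas: tuple

    def __post_init__(self):
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError("maf must be in [0, 0.5]")
        lv = tuple(self.level_betas)
        if len(lv) != 3 or not (lv[0] < lv[1] < lv[2]):
            raise ValueError("level_betas must be three strictly increasing levels")
        if lv[0] < 0 or lv[2] > 1:
            raise ValueError("level_betas must lie in [0, 1]")


@dataclasses.dataclass
class CellReference:
    """Reference methylation profiles at cell-type-discriminating probes.

    ``profiles``: markers x cell-types DataFrame of betas in [0, 1], full
    column rank, with a between-type spread of at least 0.3 at every marker.
    """

    profiles: pd.DataFrame

    @property
    def marker_probe_ids(self):
        return list(self.profiles.index)

    @property
    def cell_types(self):
        return list(self.profiles.columns)

    def validate(self) -> None:
        values = self.profiles.to_numpy()
        if ((values < 0) | (values > 1)).any():
            raise ValueError("reference profiles must lie in [0, 1]")
        if np.linalg.matrix_rank(values) < values.shape[1]:
            raise ValueError("reference profile matrix is rank deficient")


@dataclasses.dataclass
class CohortTruth:
    """Hidden ground truth of a generated cohort, for recovery testing."""

    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    ages: pd.Series
    spikes: list
    genotypes: dict  # probe_id -> per-sample genotype array (0/1/2 minor alleles)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.proportions.to_csv(outdir / "truth_cell_proportions.tsv", sep="\t")
        meta = {
            "spikes": [dataclasses.asdict(s) for s in self.spikes],
            "genotypes": {k: np.asarray(v).tolist() for k, v in self.genotypes.items()},
            "ages": {k: float(v) for k, v in self.ages.items()},
        }
        (outdir / "truth.json").write_text(json.dumps(meta, indent=1))


def generate_cell_reference(
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    n_marker_probes: int = 60,
    seed: int = 0,
    max_retries: int = 10,
) -> CellReference:
    """Simulate a curated panel of cell-type-discriminating marker probes.

    Markers are assigned round-robin to cell types; each marker is highly
    methylated (0.75-0.95) in its own type and lowly methylated (0.05-0.25)
    in the others, mimicking the discriminating CpGs of sorted-blood
    reference panels and guaranteeing a >= 0.3 between-type spread.
    """
    cell_types = list(cell_types)
    k = len(cell_types)
    if n_marker_probes < k:
        raise ValueError(
            f"need at least {k} marker probes for {k} cell types, got {n_marker_probes}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        low = rng.uniform(0.05, 0.25, size=(n_marker_probes, k))
        high = rng.uniform(0.75, 0.95, size=n_marker_probes)
        profiles = low
        owner = np.arange(n_marker_probes) % k
        profiles[np.arange(n_marker_probes), owner] = high
        if np.linalg.matrix_rank(profiles) == k:
            ids = [f"cg9{i:07d}" for i in range(n_marker_probes)]
            ref = CellReference(pd.DataFrame(profiles, index=ids, columns=cell_types))
            ref.validate()
            return ref
    raise RuntimeError("could not draw a full-rank cell reference")


def _build_annotation(config: CohortConfig, reference: CellReference) -> pd.DataFrame:
    """Deterministic synthetic manifest: markers, candidate-gene blocks, filler."""
    n = config.n_probes
    markers = reference.marker_probe_ids
    if n < len(markers):
        raise ValueError(
            f"n_probes={n} smaller than the {len(markers)} reference marker probes"
        )
    ids, chroms, positions, genes, features = [], [], [], [], []
    for i, pid in enumerate(markers):
        ids.append(pid)
        chroms.append("chr6")  # parked on one arm, away from candidate genes
        positions.append(30_000_000 + 1_000 * i)
        genes.append("")
        features.append("cell_type_marker")
    serial = 0
    for gene, (chrom, start) in CANDIDATE_GENE_LAYOUT.items():
        if len(ids) + PROBES_PER_GENE > n:
            break
        for j in range(PROBES_PER_GENE):
            if gene == "CPT1A" and j == 0:
                pid = CPT1A_PROBE
            else:
                pid = f"cg1{serial:07d}"
                serial += 1
            ids.append(pid)
            chroms.append(chrom)
            positions.append(start + j * GENE_PROBE_SPACING)
            genes.append(gene)
            features.append("Body" if j else "TSS200")
    i = 0
    while len(ids) < n:
        ids.append(f"cg5{i:07d}")
        chroms.append(f"chr{(i % 22) + 1}")
        positions.append(1_000_000 + 1_000 * (i // 22 + 1))
        genes.append("")
        features.append("")
        i += 1
    return make_annotation(ids, chroms, positions, gene=genes, gene_feature=features)


def generate_cohort(
    config: CohortConfig,
    reference: CellReference | None = None,
    spikes: Sequence[SpikeSpec] = (),
    snp_artifacts: Sequence[SnpArtifactSpec] = (),
) -> tuple[MethylationDataset, CohortTruth]:
    """Draw a full synthetic cohort; returns the dataset and its hidden truth.

    Mutation-negative samples come first in the sample sheet.  All
    randomness flows from ``config.seed``: the same seed reproduces the
    dataset exactly.
    """
    rng = np.random.default_rng(config.seed)
    if reference is None:
        reference = generate_cell_reference(
            config.cell_types, seed=int(rng.integers(2**31))
        )
    if list(reference.cell_types) != list(config.cell_types):
        raise ValueError("reference cell types do not match config.cell_types")
    annotation = _build_annotation(config, reference)
    probe_ids = list(annotation.index)
    probe_index = {p: i for i, p in enumerate(probe_ids)}
    for spike in spikes:
        if spike.probe_id not in probe_index:
            raise ValueError(f"spiked probe {spike.probe_id!r} not in annotation")

    n_neg, n_pos = config.n_group_neg, config.n_group_pos
    n = n_neg + n_pos
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    groups = ["neg"] * n_neg + ["pos"] * n_pos

    def _ages(mean, sd, size):
        a, b = (AGE_BOUNDS[0] - mean) / sd, (AGE_BOUNDS[1] - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    ages = np.concatenate(
        [
            _ages(config.age_mean_neg, config.age_sd_neg, n_neg),
            _ages(config.age_mean_pos, config.age_sd_pos, n_pos),
        ]
    )
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "age": np.round(ages, 1)}
    ).set_index("sample_id", drop=False)
    samples.index.name = None

    # true cell proportions
    w = rng.dirichlet(np.asarray(config.dirichlet_alpha, float), size=n)
    proportions = pd.DataFrame(w, index=sample_ids, columns=list(config.cell_types))

    # probes x cell-types profile matrix: reference columns at markers,
    # bimodal baselines with small per-type deviations elsewhere
    n_probes = config.n_probes
    k = len(config.cell_types)
    marker_rows = [probe_index[p] for p in reference.marker_probe_ids]
    mode = rng.choice([-2.5, 0.0, 2.5], size=n_probes, p=[0.4, 0.2, 0.4])
    base_logit = mode + rng.normal(0.0, 0.5, size=n_probes)
    type_dev = rng.normal(0.0, 0.15, size=(n_probes, k))
    profiles = expit(base_logit[:, None] + type_dev)
    profiles[marker_rows, :] = reference.profiles.to_numpy()

    mean_beta = w @ profiles.T  # samples x probes

    neg_mask = np.array([g == "neg" for g in groups])
    mean_age = float(ages.mean())
    for spike in spikes:
        j = probe_index[spike.probe_id]
        mean_beta[neg_mask, j] += spike.delta_beta
        if spike.age_slope:
            mean_beta[:, j] += spike.age_slope * (ages - mean_age)
        lo, hi = mean_beta[:, j].min(), mean_beta[:, j].max()
        if lo < 0.0 or hi > 1.0:
            raise SpikeError(
                f"spike at probe {spike.probe_id!r} pushes mean beta to "
                f"[{lo:.3f}, {hi:.3f}], outside [0, 1]"
            )

    x = logit(np.clip(mean_beta, BETA_CLIP[0], BETA_CLIP[1]))
    if config.noise_sd_logit > 0:
        x = x + rng.normal(0.0, config.noise_sd_logit, size=x.shape)
    betas = np.clip(expit(x), BETA_CLIP[0], BETA_CLIP[1])

    dataset = MethylationDataset(
        betas=pd.DataFrame(betas, index=sample_ids, columns=probe_ids),
        samples=samples,
        probes=annotation,
    )
    truth = CohortTruth(
        proportions=proportions,
        ages=pd.Series(ages, index=sample_ids),
        spikes=list(spikes),
        genotypes={},
    )
    for spec in snp_artifacts:
        dataset, geno = apply_snp_artifact(
            dataset, spec, seed=int(rng.integers(2**31))
        )
        truth.genotypes[spec.probe_id] = geno
    return dataset, truth


def mid_range_filler_probes(
    dataset: MethylationDataset, n: int, lo: float = 0.3, hi: float = 0.7
) -> list:
    """First ``n`` filler (non-marker, non-candidate-gene) probes whose mean
    beta lies in [lo, hi] — safe targets for additive spikes."""
    means = dataset.betas.mean(axis=0)
    out = [
        p
        for p in dataset.betas.columns
        if p.startswith("cg5") and lo < means[p] < hi
    ][:n]
    if len(out) < n:
        raise ValueError(f"only {len(out)} mid-range filler probes available")
    return out


def apply_snp_artifact(
    dataset: MethylationDataset,
    spec: SnpArtifactSpec,
    seed: int = 0,
    noise_sd_logit: float = 0.05,
) -> tuple[MethylationDataset, np.ndarray]:
    """Overwrite one probe with genotype-driven trimodal methylation.

    Genotypes (minor-allele counts 0/1/2) are drawn per sample under
    Hardy-Weinberg equilibrium at the spec's minor-allele frequency; the
    probe's betas become the genotype's level plus logit-scale noise.
    Returns the modified dataset and the drawn genotypes.
    """
    if spec.probe_id not in dataset.betas.columns:
        raise ValueError(f"probe {spec.probe_id!r} not present in dataset")
    rng = np.random.default_rng(seed)
    p = spec.maf
    probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    n = dataset.n_samples
    genotypes = rng.choice(3, size=n, p=probs)
    levels = np.asarray(spec.level_betas, float)
    x = logit(np.clip(levels[genotypes], BETA_CLIP[0], BETA_CLIP[1]))
    if noise_sd_logit > 0:
        x = x + rng.normal(0.0, noise_sd_logit, size=n)
    new_betas = dataset.betas.copy()
    new_betas[spec.probe_id] = np.clip(expit(x), BETA_CLIP[0], BETA_CLIP[1])
    out = MethylationDataset(
        betas=new_betas, samples=dataset.samples.copy(), probes=dataset.probes.copy()
    )
    return out, genotypes
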