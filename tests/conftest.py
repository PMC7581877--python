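import numpy as np
import pandas as pd
import pytest

from fhmeth.datasets import MethylationDataset, make_annotation
from fhmeth.synthdata import CohortConfig, generate_cell_reference, generate_cohort


@pytest.fixture(scope="session")
def reference():
    return generate_cell_reference(seed=3)


@pytest.fixture(scope="session")
def small_cohort(reference):
    """Null cohort (no spikes) at study-design sample sizes, 300 probes."""
    config = CohortConfig(n_probes=300, seed=11)
    return generate_cohort(config, reference)


def make_dataset(betas: pd.DataFrame, groups=None, ages=None) -> MethylationDataset:
    """Wrap a raw beta frame in a MethylationDataset with stub metadata."""
    n, m = betas.shape
    if groups is None:
        groups = ["neg"] * (n // 2) + ["pos"] * (n - n // 2)
    if ages is None:
        ages = np.linspace(30, 60, n)
    samples = pd.DataFrame(
        {"sample_id": list(betas.index), "group": groups, "age": ages}
    ).set_index("sample_id", drop=False)
    samples.index.name = None
    probes = make_annotation(
        list(betas.columns),
        chrom=["chr1"] * m,
        pos=np.arange(1, m + 1) * 1000,
    )
    return MethylationDataset(betas=betas, samples=samples, probes=probes)


@pytest.fixture
def tiny_dataset():
    rng = np.random.default_rng(0)
    betas = pd.DataFrame(
        rng.uniform(0.1, 0.9, size=(6, 5)),
        index=[f"S{i}" for i in range(6)],
        columns=[f"cg{i:08d}" for i in range(5)],
    )
    return make_dataset(betas)
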