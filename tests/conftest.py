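import numpy as np
import pandas as pd
import pytest

from riboslide import SimConfig, simulate_experiment
from riboslide.simulate import library_columns


@pytest.fixture(scope="session")
def small_experiment():
    """One modest seeded experiment shared by read-only tests."""
    cfg = SimConfig(
        n_genes=400, depth_rpf=400_000, depth_mrna=400_000, seed=11
    )
    annotations, counts, truth = simulate_experiment(cfg)
    return cfg, annotations, counts, truth


def random_count_table(rng: np.random.Generator, n_genes: int = 50,
                       n_replicates: int = 2, high: int = 5000) -> pd.DataFrame:
    cols = library_columns(n_replicates)
    return pd.DataFrame(
        rng.integers(0, high, size=(n_genes, len(cols))),
        index=pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id"),
        columns=pd.MultiIndex.from_tuples(
            cols, names=["condition", "assay", "replicate"]
        ),
    )
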