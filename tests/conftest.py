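import numpy as np
import pandas as pd
import pytest

from agingaccel import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at reduced size, with planted signal."""
    cfg = syn.SyntheticConfig(
        n_genes=80, n_young=40, n_old_normal=45, n_pd=40,
        n_aging_genes=10, n_pd_genes=6, n_diff_edges=6,
        seed=11,
    )
    return syn.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_matrix(values, genes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{i:03d}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="GENE_SYMBOL"), columns=samples)
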