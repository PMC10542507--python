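import numpy as np
import pandas as pd
import pytest

from oefit import synthetic
from oefit.data_model import CountMatrix, SampleSheet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sheet():
    """Three replicates of one strain at generations 0 and 10."""
    rows = []
    for rep in (1, 2, 3):
        for gen in (0.0, 10.0):
            rows.append(
                dict(sample_id=f"S_g{gen:g}_r{rep}", strain="S",
                     condition="NaCl", generation=gen, replicate=rep)
            )
    return SampleSheet(pd.DataFrame(rows))


def make_counts(values, sheet=None, genes=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = sheet.sample_ids if sheet else [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=cols))


@pytest.fixture(scope="session")
def recovery_pool():
    """The standard parameter-recovery pool: 1,000 genes, depth 1e7, 3 reps."""
    cfg = synthetic.PoolSimConfig(
        n_genes=1000, strains=("S1",), depth=10_000_000, n_replicates=3, seed=1
    )
    return synthetic.simulate_pool_growth(cfg)
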