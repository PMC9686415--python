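import numpy as np
import pandas as pd
import pytest

from crispmeth import SimulationConfig, simulate_all


def small_config(seed: int = 1, **kw) -> SimulationConfig:
    """Desk-scale simulation used by unit tests (full scale is exercised in
    the acceptance suite)."""
    defaults = dict(
        seed=seed, n_chroms=1, chrom_length=200_000, n_genes=20,
        n_planted_dmrs=5, n_intergenic_islands=5,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_all(small_config())


@pytest.fixture(scope="session")
def pooled_group_a(small_bundle):
    tables, _ = small_bundle.group_tables()
    return (
        pd.concat(tables, ignore_index=True)
        .groupby(["chrom", "pos", "strand", "context"], observed=True)
        [["meth", "total"]]
        .sum()
        .reset_index()
    )


def make_calls(rows) -> pd.DataFrame:
    """Build a call table from (chrom, pos, strand, context, meth, total)."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth", "total"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
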