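import numpy as np
import pandas as pd
import pytest

from methlink.synthetic import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-gene synthetic dataset shared by fast tests."""
    params = SimulationParams(n_genes=40, n_dm_sites=20, seed=11)
    genes, islands, calls, expr, de, truth = simulate_dataset(params)
    return {
        "params": params,
        "genes": genes,
        "islands": islands,
        "calls": calls,
        "expr": expr,
        "de": de,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def big_dataset():
    """A 400-gene dataset for statistical sanity checks."""
    params = SimulationParams(n_genes=400, seed=5)
    genes, islands, calls, expr, de, truth = simulate_dataset(params)
    return {
        "params": params,
        "genes": genes,
        "islands": islands,
        "calls": calls,
        "expr": expr,
        "de": de,
        "truth": truth,
    }


def make_calls(rows):
    """Build a call frame from (chrom, pos, strand, context, sample, n_meth, n_unmeth)."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "context", "sample_id", "n_meth", "n_unmeth"],
    )


def make_genes(rows):
    """Build a gene frame from (gene_id, chrom, strand, tss)."""
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
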