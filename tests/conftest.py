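import numpy as np
import pandas as pd
import pytest

import spinpop as sp


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two well-separated pure-ancestry populations, 20+20 samples."""
    cfg = sp.SimConfig(n_pops=2, n_per_pop=20, n_loci=500,
                       chrom_lengths=(5_000_000,), F=0.2, seed=101)
    gm, truth = sp.simulate_genotypes(cfg)
    groups = {"A": np.arange(20), "B": np.arange(20, 40)}
    return gm, truth, groups


@pytest.fixture(scope="session")
def demo_matrix():
    from spinpop.datasets import cascade_demo_matrix

    return cascade_demo_matrix()


def make_matrix(dosages, positions=None, chrom="chr1", quals=None,
                kinds=None, depths=None):
    """Small helper to hand-build a GenotypeMatrix from a dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    positions = positions if positions is not None else \
        np.arange(1, L + 1) * 100
    sites = pd.DataFrame({
        "chrom": [chrom] * L, "pos": positions,
        "ref": ["A"] * L, "alt": ["G"] * L,
        "qual": quals if quals is not None else [50.0] * L,
        "kind": kinds if kinds is not None else ["snp"] * L,
    })
    samples = pd.DataFrame({"id": [f"S{i}" for i in range(n)]})
    return sp.GenotypeMatrix(dosages, sites, samples, depths)
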