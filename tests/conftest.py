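import numpy as np
import pandas as pd
import pytest

from herdscan.datatypes import GenotypeMatrix
from herdscan.synth import SimulationConfig, simulate_population, simulate_taxa


def make_genotypes(calls, chroms=None, ids=None) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=float)
    n, p = calls.shape
    if chroms is None:
        chroms = ["1"] * p
    snps = pd.DataFrame(
        {"chrom": [str(c) for c in chroms], "pos": np.arange(1, p + 1)},
        index=pd.Index([f"s{j}" for j in range(p)], name="snp"),
    )
    if ids is None:
        ids = [f"i{i}" for i in range(n)]
    return GenotypeMatrix(calls, ids, snps)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic mid-sized synthetic cohort shared across tests."""
    config = SimulationConfig(
        seed=20260929, n_individuals=120, n_snps=400, n_taxa=40,
        taxon_h2=0.3, breed_slope=0.5,
    )
    truth, geno, meta = simulate_population(config)
    abundance = simulate_taxa(truth, geno, config)
    return config, truth, geno, abundance, meta
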