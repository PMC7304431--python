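import warnings

import numpy as np
import pytest

from hetfit.genotype_io import GenotypeTable, IndividualRecord
from hetfit.synthetic_data import FMixture, SimulationConfig, simulate_dataset


def make_table(calls, loci=None, meta=None):
    """Tiny GenotypeTable from a list of per-individual call lists."""
    n = len(calls)
    L = len(calls[0])
    loci = loci or [f"L{j}" for j in range(L)]
    individuals = []
    for k in range(n):
        kw = dict(id=f"I{k}", sex="female", year=2006)
        if meta:
            kw.update(meta[k])
        individuals.append(IndividualRecord(**kw))
    arr = np.empty((n, L, 2), dtype=object)
    for k in range(n):
        for j in range(L):
            arr[k, j] = calls[k][j] if calls[k][j] is not None else (None, None)
    return GenotypeTable(individuals=individuals, loci=loci, calls=arr)


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale synthetic dataset (168 x 32, defaults)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def outbred_dataset():
    """Large outbred dataset (f = 0 everywhere), no missing calls."""
    cfg = SimulationConfig(
        n_individuals=2000, f_dist=FMixture(pi0=1.0), missing_rate=0.0,
        seed=21,
    )
    return simulate_dataset(cfg)
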