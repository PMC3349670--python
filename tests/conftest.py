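import numpy as np
import pandas as pd
import pytest

from streamscape.datasets import GenotypeDataset


def make_dataset(pops, calls, loci=None, regions=None):
    """Build a GenotypeDataset from a population list and a call array."""
    calls = np.asarray(calls)
    loci = loci or [f"L{j + 1}" for j in range(calls.shape[1])]
    ind = pd.DataFrame({
        "id": [f"i{k}" for k in range(len(pops))],
        "population": pops,
    })
    if regions is not None:
        ind["region"] = regions
    return GenotypeDataset(ind, list(loci), calls)


@pytest.fixture
def toy_three_pop():
    """3 populations x 4 diploids x 2 loci in 2 regions, fixed genotypes."""
    rng = np.random.default_rng(42)
    pops = ["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4
    regions = ["r1"] * 8 + ["r2"] * 4
    calls = rng.integers(10, 14, size=(12, 2, 2))
    return make_dataset(pops, calls, regions=regions)


@pytest.fixture
def fixed_difference_pair():
    """Two populations fixed for different alleles at one locus."""
    calls = np.zeros((8, 1, 2), dtype=int)
    calls[:4] = 100
    calls[4:] = 102
    return make_dataset(["A"] * 4 + ["B"] * 4, calls)
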