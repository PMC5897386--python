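import numpy as np
import pandas as pd
import pytest

from occnet.containers import OtuTable
from occnet.simulate import desk_scale_config, simulate_dataset


@pytest.fixture(scope="session")
def desk_data():
    """One desk-scale simulated dataset shared across tests."""
    return simulate_dataset(desk_scale_config(1))


@pytest.fixture()
def toy_table():
    """3 OTUs x 6 samples (2 sites x 3 replicates) hand-built table."""
    counts = pd.DataFrame(
        {
            "S1R1": [5, 0, 1],
            "S1R2": [3, 0, 2],
            "S1R3": [4, 1, 0],
            "S2R1": [0, 7, 1],
            "S2R2": [0, 6, 0],
            "S2R3": [1, 9, 2],
        },
        index=["OTU_a", "OTU_b", "OTU_c"],
    )
    taxonomy = pd.Series(
        {
            "OTU_a": "k__Bacteria; p__Actinobacteria; c__Actinobacteriaia; o__oActino; f__fActino; g__Genus001",
            "OTU_b": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__oProteo; f__fProteo; g__Nitrospira",
            "OTU_c": "k__Bacteria; p__Firmicutes; c__Firmicutesia; o__oFirmic; f__fFirmic; g__Genus003",
        }
    )
    meta = pd.DataFrame(
        {
            "site": [1, 1, 1, 2, 2, 2],
            "replicate": [1, 2, 3, 1, 2, 3],
            "section": [1, 1, 1, 2, 2, 2],
        },
        index=counts.columns,
    )
    return OtuTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)


def random_otu_table(rng: np.random.Generator, n_otus: int = 8, n_sites: int = 2) -> OtuTable:
    samples = [f"S{s}R{r}" for s in range(1, n_sites + 1) for r in (1, 2, 3)]
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(n_otus, len(samples))),
        index=[f"OTU_{i:03d}" for i in range(n_otus)],
        columns=samples,
    )
    taxonomy = pd.Series(
        [
            f"k__Bacteria; p__Phy{i % 3}; c__C{i}; o__O{i}; f__F{i}; g__G{i}"
            for i in range(n_otus)
        ],
        index=counts.index,
    )
    meta = pd.DataFrame(
        {
            "site": [int(s[1]) for s in samples],
            "replicate": [int(s[3]) for s in samples],
            "section": [1 if int(s[1]) <= n_sites // 2 else 2 for s in samples],
        },
        index=samples,
    )
    return OtuTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)
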