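import numpy as np
import pandas as pd
import pytest

from wolbiome import CommunitySimSpec, OtuTable, simulate_otu_table


@pytest.fixture
def tiny_table() -> OtuTable:
    """Three samples, four OTUs in two genera, handcrafted counts."""
    counts = pd.DataFrame(
        [[5, 3, 2, 0], [0, 10, 0, 10], [1, 1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3", "o4"],
    )
    taxonomy = pd.Series(
        ["Bacteria;X;GenA", "Bacteria;X;GenA", "Bacteria;Y;GenB", "Bacteria;Y;GenB"],
        index=counts.columns,
    )
    return OtuTable(counts, taxonomy)


@pytest.fixture(scope="session")
def sim_survey():
    """A moderate multi-population survey used by several test modules."""
    spec = CommunitySimSpec(
        n_populations=6,
        samples_per_population=4,
        depth=5000,
        n_taxa=200,
        symbiont_mean_prop=0.8,
        infection_rate=1.0,
        seed=123,
    )
    return simulate_otu_table(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
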