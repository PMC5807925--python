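import pandas as pd
import pytest

from commstable import CountTable


@pytest.fixture
def toy_counts() -> CountTable:
    """5 samples x 5 OTUs with mixed depths and prevalences."""
    df = pd.DataFrame(
        [
            [12000, 0, 300, 5, 0],       # deep
            [9000, 500, 400, 0, 99],     # shallow (9,999)
            [15000, 200, 0, 0, 10],      # deep
            [20000, 0, 0, 0, 0],         # deep
            [11000, 100, 250, 0, 2],     # deep
        ],
        index=[f"S{i}" for i in range(1, 6)],
        columns=[f"OTU{i}" for i in range(1, 6)],
    )
    return CountTable(df)


@pytest.fixture
def small_block_table():
    """Seeded compositional table with two planted 5-OTU blocks."""
    from commstable import BlockSpec, simulate_block_table

    spec = BlockSpec(n_samples=120, block_sizes=(5, 5),
                     n_background_otus=10, rho_within=0.8,
                     depth_range=(15_000, 30_000), seed=7)
    return simulate_block_table(spec)
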