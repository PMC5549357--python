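import numpy as np
import pandas as pd
import pytest

from consenrank.config import SimConfig
from consenrank.consensus import ConsensusTable


def make_table(ordered_genes, n_methods=12):
    """ConsensusTable with the given gene order and linear ConsenScore."""
    N = len(ordered_genes)
    rank = np.arange(1, N + 1)
    df = pd.DataFrame(
        {
            "n_methods": n_methods,
            "mean_norm": (N - rank + 1) / N,
            "gene_score": (N - rank + 1) / N,
            "tiebreak": (N - rank + 1) / N,
            "rank": rank,
            "consen_score": (N - rank + 1) / N,
        },
        index=pd.Index(ordered_genes, name="gene_id"),
    )
    return ConsensusTable(df=df, n_methods=n_methods)


@pytest.fixture
def small_config():
    return SimConfig(
        n_genes=300,
        n_positives=15,
        n_methods=4,
        n_communities=3,
        community_size=5,
        community_overlap=0,
        n_network_extra=20,
        n_de_genes=60,
        seed=11,
    )
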