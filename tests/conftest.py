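import numpy as np
import pandas as pd
import pytest

from plankton_assembly import (
    CommunityTable, EnvTable, PhyloTree, SampleMetadata,
)


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    return pd.DataFrame(
        [[6, 2, 0, 1], [2, 6, 0, 3], [0, 0, 5, 5]],
        index=["S1", "S2", "S3"],
        columns=["ASV_1", "ASV_2", "ASV_3", "ASV_4"],
    )


@pytest.fixture
def toy_table(toy_counts) -> CommunityTable:
    return CommunityTable(toy_counts.copy())


@pytest.fixture
def grouped_table(toy_counts) -> CommunityTable:
    group = pd.Series(["April", "April", "May"], index=toy_counts.index)
    return CommunityTable(toy_counts.copy(), group)


@pytest.fixture
def cherry_tree() -> PhyloTree:
    # ASV_1 sister to (ASV_2, ASV_3); ASV_4 outgroup
    nwk = "((ASV_1:1.0,(ASV_2:0.5,ASV_3:0.5):0.5):1.0,ASV_4:2.0);"
    return PhyloTree.from_newick(nwk, is_path=False)


@pytest.fixture
def toy_env() -> EnvTable:
    return EnvTable(pd.DataFrame(
        {
            "temperature": [18.0, 22.0, 26.0],
            "pH": [7.8, 8.1, 8.6],
            "TP": [0.05, 0.10, 0.30],
            "TN": [1.0, 1.5, 3.0],
            "COD": [10.0, 20.0, 35.0],
            "Chl_a": [5.0, 30.0, 120.0],
        },
        index=["S1", "S2", "S3"],
    ))


@pytest.fixture
def toy_meta() -> SampleMetadata:
    return SampleMetadata(pd.DataFrame(
        {
            "group": ["April", "April", "May"],
            "latitude": [30.50, 30.55, 30.60],
            "longitude": [114.30, 114.35, 114.40],
        },
        index=["S1", "S2", "S3"],
    ))
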