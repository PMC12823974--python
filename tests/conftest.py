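import numpy as np
import pandas as pd
import pytest

from npcoupling import GeneratorConfig, generate_dataset
from npcoupling.tableio import CountTable, NutrientTable


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic dataset, shared read-only across tests."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture()
def toy_counts():
    """Tiny handmade raw count table (3 sites x 4 features)."""
    data = pd.DataFrame(
        {
            "ASV1": [40, 10, 30],
            "ASV2": [30, 50, 20],
            "ASV3": [20, 30, 25],
            "ASV4": [10, 10, 25],
        },
        index=["S1", "S2", "S3"],
    )
    return CountTable(data, marker_group="16S")


def make_nutrients(rows: dict[str, list[float]]) -> NutrientTable:
    return NutrientTable(pd.DataFrame(rows).T.set_axis(
        ["TN", "NAG", "net_Nmin", "N_inorg", "TP", "AP", "AKP"], axis=1
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
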