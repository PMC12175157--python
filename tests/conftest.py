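import numpy as np
import pandas as pd
import pytest

from qsarcons import PredictionTable, SyntheticConfig, generate_dataset, split_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition ensemble with challenge-like split sizes."""
    cfg = SyntheticConfig(n_compounds=1500, seed=0)
    return split_dataset(generate_dataset(cfg), seed=0)


@pytest.fixture()
def tiny_table():
    """Three compounds, three models, AD flags and STDs, hand-checkable."""
    return PredictionTable(
        pd.DataFrame(
            {
                "compound_id": ["a", "b", "c"],
                "y_exp": [12.0, 25.0, 60.0],
                "split": ["train", "test", "test"],
                "pred_m1": [10.0, 20.0, 50.0],
                "pred_m2": [20.0, 30.0, 55.0],
                "pred_m3": [30.0, 25.0, 66.0],
                "std_m1": [1.0, 2.0, 3.0],
                "std_m2": [1.5, 2.5, 3.5],
                "std_m3": [0.5, 1.0, 1.5],
                "in_ad_m1": [1, 1, 0],
                "in_ad_m2": [1, 0, 0],
                "in_ad_m3": [0, 0, 1],
            }
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
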