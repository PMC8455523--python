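import numpy as np
import pandas as pd
import pytest

import coexsweep as cx


@pytest.fixture(scope="session")
def small_planted():
    """40+40 samples, one male module (10 genes, rho 0.9), 50 background."""
    config = cx.SimulationConfig(
        n_females=40,
        n_males=40,
        n_background_genes=50,
        modules=(cx.ModuleSpec(n_genes=10, target_group="male", rho_on=0.9),),
        seed=11,
    )
    expr, metadata, truth = cx.generate_dataset(config)
    return expr, metadata, truth


@pytest.fixture(scope="session")
def small_log(small_planted):
    expr, metadata, truth = small_planted
    return cx.log_transform(expr), metadata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["A", "B", "C", "D"],
            "sex": ["female", "male", "female", "male"],
            "age_decade": ["40-49", "50-59", "60-69", "20-29"],
            "rin": [7.0, 8.0, 6.5, 9.0],
            "tissue": ["t1", "t1", "t1", "t1"],
        }
    )
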