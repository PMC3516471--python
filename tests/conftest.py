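import pandas as pd
import pytest

from ferrotime import diffexp, preprocess, synthdata


@pytest.fixture(scope="session")
def small_config() -> synthdata.SimulationConfig:
    return synthdata.SimulationConfig(
        seed=7,
        n_mrna=200,
        n_asrna=30,
        n_srna=60,
        n_control=100,
        n_unexpressed=30,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> synthdata.SyntheticDataset:
    return synthdata.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_expr(small_dataset) -> preprocess.ExpressionSet:
    return preprocess.preprocess(
        small_dataset.probes, small_dataset.probe_map, small_dataset.design
    )


@pytest.fixture(scope="session")
def small_fc(small_expr) -> pd.DataFrame:
    return diffexp.differential_expression(small_expr)
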