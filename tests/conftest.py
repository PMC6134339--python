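import warnings

import numpy as np
import pandas as pd
import pytest

from assocnet.ingest import ExpressionSet, PhenoTable
from assocnet.synthdata import SynthConfig, generate_annotations, generate_dataset

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Desk-scale study conditions: 2 planted modules, moderate noise."""
    return SynthConfig(
        n_samples_per_stratum=10,
        n_celltypes=4,
        n_markers_per_cell=15,
        n_planted_modules=2,
        module_size=30,
        n_noise_probes=300,
        noise_sd=0.3,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, small_dataset):
    _, _, truth = small_dataset
    return generate_annotations(small_config, truth)


@pytest.fixture()
def tiny_pheno() -> PhenoTable:
    data = pd.DataFrame(
        {
            "class": ["control"] * 4 + ["case"] * 4,
            "sex": ["F", "M"] * 4,
            "age": [30, 40, 35, 45, 32, 41, 37, 44],
        },
        index=[f"s{i}" for i in range(8)],
    )
    return PhenoTable(
        data=data,
        var_types={"class": "categorical", "sex": "categorical", "age": "numeric"},
        class_var="class",
        strat_var="sex",
    )


def make_expr(values: np.ndarray, normalized: bool = True, prefix: str = "p") -> ExpressionSet:
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return ExpressionSet(values=df, normalized=normalized)
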