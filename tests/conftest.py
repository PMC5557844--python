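import numpy as np
import pandas as pd
import pytest

import stressdiel as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimConfig(n_genes=300, seed=11)


@pytest.fixture(scope="session")
def stress_data(small_config):
    return sd.generate_stress_series(small_config)


@pytest.fixture(scope="session")
def diurnal_data(small_config):
    return sd.generate_diurnal_course(small_config)


@pytest.fixture(scope="session")
def fold_changes(stress_data):
    matrix, meta, _ = stress_data
    return sd.fold_change(sd.log2_normalize(matrix), meta)


@pytest.fixture()
def toy_matrix():
    """3 genes x 4 samples, one stress/mock pair per replicate."""
    values = pd.DataFrame(
        {
            "s_stress_r1": [512.0, 8.0, 2.0],
            "s_mock_r1": [256.0, 8.0, 4.0],
            "s_stress_r2": [1024.0, 16.0, 2.0],
            "s_mock_r2": [256.0, 16.0, 8.0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return sd.ExpressionMatrix(values=values, scale="linear")


@pytest.fixture()
def toy_metadata():
    rows = []
    for rep in (1, 2):
        for cond in ("stress", "mock"):
            rows.append(
                {
                    "sample_id": f"s_{cond}_r{rep}",
                    "series_id": "s",
                    "stress_type": "drought",
                    "condition": cond,
                    "replicate": rep,
                    "stage": np.nan,
                    "day": np.nan,
                    "hour": np.nan,
                }
            )
    return pd.DataFrame(rows)
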