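import numpy as np
import pandas as pd
import pytest

import pedmeth as pm


@pytest.fixture(scope="session")
def small_config():
    return pm.SimulationConfig(
        n_genes=400,
        samples_per_dataset=20,
        tumor_types={"wilms": 20, "neuroblastoma": 20},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_normals(small_config):
    return pm.simulate_normals(small_config)


@pytest.fixture(scope="session")
def small_tumors(small_config, small_normals):
    return pm.simulate_tumors(small_config, small_normals)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_matrix(values, scale="beta", prefix="f", samples=None):
    values = np.asarray(values, dtype=float)
    index = [f"{prefix}{i}" for i in range(values.shape[0])]
    columns = samples or [f"s{j}" for j in range(values.shape[1])]
    return pm.MethylationMatrix(pd.DataFrame(values, index=index, columns=columns), scale)


def make_metadata(sample_ids, dataset_ids=None, sexes=None, condition="normal", tumor_type=None):
    n = len(sample_ids)
    dataset_ids = dataset_ids or ["d0"] * n
    sexes = sexes or ["female" if i % 2 else "male" for i in range(n)]
    return pm.validate_metadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "dataset_id": dataset_ids,
                "sex": sexes,
                "condition": condition,
                "tumor_type": [tumor_type] * n,
            }
        )
    )
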