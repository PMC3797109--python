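import numpy as np
import pandas as pd
import pytest

import carryover as co


@pytest.fixture(scope="session")
def study_dataset():
    """Study-scale synthetic dataset (6 years, 216 birds) with resightings."""
    cfg = co.SimConfig(seed=101)
    ds = co.generate_dataset(cfg)
    rs = co.generate_resightings(ds, cfg)
    return ds, rs, cfg


@pytest.fixture(scope="session")
def preprocessed(study_dataset):
    """Analysis-ready table from the study-scale dataset (generative SMA 3.4)."""
    ds, rs, _ = study_dataset
    return co.preprocess_dataset(ds.birds, ds.nao, rs, sma_slope=3.4, reference_length_mm=89.6)


@pytest.fixture(scope="session")
def tiny_glmm_data():
    """3 groups x 4 observations; small counts."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "n_offspring": rng.poisson(1.5, 12),
            "mass_z": rng.standard_normal(12),
            "nao_z": rng.standard_normal(12),
            "year": np.repeat([2005, 2006, 2007], 4),
        }
    )


@pytest.fixture(scope="session")
def glmm_fixture_50(study_dataset):
    """<= 50 observation slice of the study dataset for oracle comparisons."""
    ds, rs, _ = study_dataset
    prep = co.preprocess_dataset(ds.birds, ds.nao, rs, sma_slope=3.4)
    return prep.data.iloc[:48].reset_index(drop=True)
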