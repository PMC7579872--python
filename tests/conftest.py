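import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import lfcmeta as lm

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohorts():
    """The eleven-study catalogue."""
    return lm.cohort_catalogue()


@pytest.fixture(scope="session")
def spiked_bundle():
    """Small synthetic bundle: one spiked gene among nulls, mild heterogeneity."""
    cfg = lm.SyntheticConfig(
        n_genes=30, true_lfc={"SPP1": 2.64}, tau2=0.05, sigma2=1.0, seed=7
    )
    return cfg, lm.generate_studies(cfg)


def toy_dataset(values, labels, meta=None, **meta_kwargs):
    """Build a small ExpressionDataset from a dict of gene -> row values."""
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    lab = pd.Series(labels, index=df.columns)
    n_case = int((lab == lm.CASE).sum())
    n_control = int((lab == lm.CONTROL).sum())
    if meta is None:
        meta = lm.StudyMeta(
            geo_id=meta_kwargs.pop("geo_id", "GSE_TOY"), study_name="toy",
            n_control=n_control, n_case=n_case, country="USA", study_age=1.0,
            **meta_kwargs,
        )
    return lm.ExpressionDataset(values=df, labels=lab, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
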