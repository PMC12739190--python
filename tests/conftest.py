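import numpy as np
import pandas as pd
import pytest

from ddrs import DDRSModel, WeightConfig, load_calibrated_config
from ddrs.simulate import generate_profiles


@pytest.fixture(scope="session")
def calibrated_cohort() -> pd.DataFrame:
    """The study cohort: 10,000 profiles from the frozen calibrated generator."""
    return generate_profiles(load_calibrated_config(n_profiles=10_000, seed=42))


@pytest.fixture(scope="session")
def fitted_results(calibrated_cohort):
    return DDRSModel(calibrated_cohort).fit()


@pytest.fixture
def default_weights() -> WeightConfig:
    return WeightConfig()


def make_cohort(s, a, k, q, medas=None, dpi=None, hei=None) -> pd.DataFrame:
    """Hand-built cohort from component arrays (indices default to neutral values)."""
    s = np.asarray(s, dtype=float)
    n = s.size
    return pd.DataFrame({
        "sugar_S": s,
        "acid_A": np.asarray(a, dtype=float),
        "protective_K": np.asarray(k, dtype=float),
        "quality_Q": np.asarray(q, dtype=float),
        "medas_raw": np.full(n, 7) if medas is None else np.asarray(medas),
        "dpi": np.full(n, 50.0) if dpi is None else np.asarray(dpi, dtype=float),
        "hei": np.full(n, 50.0) if hei is None else np.asarray(hei, dtype=float),
    })
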