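import numpy as np
import pandas as pd
import pytest

from clockscape import AnalysisConfig, OmicsMatrix
from clockscape.simulate import PlantedTruth, default_truth, generate_cohort


@pytest.fixture
def config():
    return AnalysisConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale cohort with the full planted scenario."""
    return generate_cohort(AnalysisConfig(seed=11), truth=default_truth())


@pytest.fixture(scope="session")
def null_cohort():
    """A pure-noise cohort (empty planted truth)."""
    return generate_cohort(AnalysisConfig(seed=13), truth=PlantedTruth())


def random_matrix(rng, kind, n_features=8, n_samples=5, missing_rate=0.15):
    """A random OmicsMatrix of the given kind with some missing cells."""
    if kind == "methylation":
        vals = rng.uniform(0, 1, size=(n_features, n_samples))
    elif kind == "cnv":
        vals = rng.choice([-2, -1, 0, 1, 2], size=(n_features, n_samples)).astype(float)
    else:
        vals = rng.normal(0, 1, size=(n_features, n_samples))
        if kind in ("expression", "auc"):
            vals = np.exp(vals)
    mask = rng.uniform(size=vals.shape) < missing_rate
    vals[mask] = np.nan
    df = pd.DataFrame(
        vals,
        index=[f"F{i}" for i in range(n_features)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return OmicsMatrix(df, kind=kind)
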