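import numpy as np
import pandas as pd
import pytest

from grazemulti.standardization import minmax_standardize
from grazemulti.synthetic import SyntheticScenario, generate


@pytest.fixture(scope="session")
def experiment():
    """One default 6-block x 4-treatment synthetic experiment."""
    return generate(SyntheticScenario(seed=42))


@pytest.fixture(scope="session")
def design(experiment):
    return experiment[0]


@pytest.fixture(scope="session")
def raw_functions(experiment):
    return experiment[1]


@pytest.fixture(scope="session")
def richness(experiment):
    return experiment[2]


@pytest.fixture(scope="session")
def std_functions(raw_functions):
    return minmax_standardize(raw_functions)


@pytest.fixture(scope="session")
def std_richness(richness):
    return minmax_standardize(richness)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_std_table(rng, n_plots=24, n_vars=12, prefix="f"):
    """A random plots x variables table already scaled to [0, 1]."""
    from grazemulti.standardization import StandardizedTable

    vals = rng.random((n_plots, n_vars))
    # force each column to attain 0 and 1 so the [0,1] invariant holds exactly
    vals = (vals - vals.min(axis=0)) / (vals.max(axis=0) - vals.min(axis=0))
    df = pd.DataFrame(vals, columns=[f"{prefix}{i:02d}" for i in range(n_vars)])
    df.insert(0, "plot_id", [f"p{i:03d}" for i in range(n_plots)])
    return StandardizedTable(df)
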