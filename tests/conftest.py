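import numpy as np
import pandas as pd
import pytest

from wheatgpc import SceneParams, build_variable_table, generate_samples

#: Eq-style published four-variable GPC model used in worked examples
PAPER_PREDICTORS = ["NDVI", "SIPI", "PSRI", "EVI"]
PAPER_COEFFICIENTS = [3.873, 1.696, 2.862, -1.276]
PAPER_INTERCEPT = 5.821


@pytest.fixture(scope="session")
def default_params() -> SceneParams:
    return SceneParams()


@pytest.fixture(scope="session")
def samples_255() -> pd.DataFrame:
    """One study-sized replicate (255 field points)."""
    return generate_samples(SceneParams(n_samples=255, seed=7))


@pytest.fixture(scope="session")
def table_255(samples_255):
    return build_variable_table(samples_255)


@pytest.fixture(scope="session")
def big_samples() -> pd.DataFrame:
    """Large draw for Monte-Carlo checks of the calibrated defaults."""
    return generate_samples(SceneParams(n_samples=5000, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
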