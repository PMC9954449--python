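import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_categories() -> np.ndarray:
    """5 cases x 4 observers; pairwise OPAs in {0.6, 0.8}, OPA(4) = 0.4."""
    return np.array(
        [
            [0, 0, 0, 0],
            [0, 0, 1, 0],
            [1, 1, 1, 1],
            [2, 2, 2, 0],
            [0, 1, 0, 0],
        ]
    )


@pytest.fixture
def toy_ratings() -> pd.DataFrame:
    rng = np.random.RandomState(7)
    values = rng.uniform(0, 100, size=(6, 4))
    return pd.DataFrame(
        values,
        index=[f"case_{i}" for i in range(6)],
        columns=[f"obs_{j}" for j in range(4)],
    )


def random_categorical(rng: np.random.RandomState, n_cases: int, n_obs: int,
                       n_categories: int = 3) -> np.ndarray:
    """Random ordinal matrix with some case-level structure (not pure noise)."""
    base = rng.randint(0, n_categories, size=n_cases)
    flip = rng.random_sample((n_cases, n_obs)) < 0.3
    noise = rng.randint(0, n_categories, size=(n_cases, n_obs))
    return np.where(flip, noise, base[:, None])
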