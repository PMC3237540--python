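import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def halfsib_crosses() -> pd.DataFrame:
    """Two sires x two dams each, 3 offspring per family."""
    rows = []
    for s in range(2):
        for d in range(2):
            rows.append({"sire": f"s{s}", "dam": f"d{s}_{d}", "n_offspring": 3})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20080616)
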