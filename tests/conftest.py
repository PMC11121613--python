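import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from uvbflav.design import StudyDesign

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def design() -> StudyDesign:
    return StudyDesign(seed=7)


@pytest.fixture
def two_group_design() -> StudyDesign:
    return StudyDesign(groups=("M", "N"), seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(design) -> pd.DataFrame:
    """A 20-feature intensity matrix with constant within-group values."""
    rng = np.random.default_rng(3)
    base = rng.uniform(100, 1000, size=20)
    cols = {}
    for g in design.groups:
        for s in design.samples_of(g):
            cols[s] = base
    return pd.DataFrame(cols, index=[f"F{i:02d}" for i in range(20)])
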