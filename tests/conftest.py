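import numpy as np
import pandas as pd
import pytest

from leafspectra import EffectModel, SurveyDesign, simulate_survey


@pytest.fixture(scope="session")
def default_bundle():
    """One default 300-pair synthetic survey shared across read-only tests."""
    return simulate_survey(design=SurveyDesign(), model=EffectModel(), seed=20260919)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_trait_table(rng):
    """A 12-unit positive trait table with known structure."""
    n = 12
    frame = pd.DataFrame(
        {
            "unit_id": [f"u{i}" for i in range(n)],
            "leaf_area": rng.uniform(10, 60, n),
            "sla": rng.uniform(80, 220, n),
            "ldmc": rng.uniform(150, 350, n),
            "chlorophyll": rng.uniform(20, 50, n),
            "leaf_c": rng.uniform(38, 47, n),
            "leaf_n": rng.uniform(1.2, 3.2, n),
        }
    )
    frame["leaf_cn"] = frame["leaf_c"] / frame["leaf_n"]
    return frame
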