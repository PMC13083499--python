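import numpy as np
import pandas as pd
import pytest

from ptesrisk.data_model import ConcentrationTable, ToxParamRegistry
from ptesrisk.synthetic import FISH_ANCHORS, WATER_ANCHORS, SyntheticSpec, generate

# the 13 quantified mean muscle concentrations (mg/kg ww); boron excluded
FISH_MEANS_13 = {k: v for k, v in FISH_ANCHORS.items() if k != "B"}
WATER_MEANS_13 = {k: v for k, v in WATER_ANCHORS.items() if k != "B"}


@pytest.fixture(scope="session")
def registry() -> ToxParamRegistry:
    return ToxParamRegistry.default()


@pytest.fixture(scope="session")
def synthetic_pair():
    """Default-condition synthetic survey (15 stations × 14 elements)."""
    return generate(SyntheticSpec(seed=20260925))


@pytest.fixture
def tiny_fish_table() -> ConcentrationTable:
    values = pd.DataFrame(
        {"As": [1.0, 2.0, 4.0], "Zn": [30.0, 40.0, 50.0], "Pb": [0.1, 0.2, 0.3]},
        index=["S1", "S2", "S3"],
    )
    coords = pd.DataFrame(
        {"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 0.5]}, index=values.index
    )
    return ConcentrationTable(medium="fish", values=values, coordinates=coords)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
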