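import numpy as np
import pandas as pd
import pytest

from cihkit import IndexConfig, IndicatorSpec, eswb2015


@pytest.fixture(scope="session")
def eswb_config():
    return eswb2015()


@pytest.fixture
def one_pillar_config():
    """Two opposed indicators in a single pillar (the hand-worked toy)."""
    return IndexConfig(
        indicators=(
            IndicatorSpec("I1", "p", "positive"),
            IndicatorSpec("I2", "p", "positive"),
        )
    )


@pytest.fixture
def opposed_panel():
    """Three units whose two indicators run in opposite directions."""
    return pd.DataFrame(
        {"I1": [0.0, 1.0, 2.0], "I2": [2.0, 1.0, 0.0]}, index=["A", "B", "C"]
    )


@pytest.fixture
def two_pillar_config():
    return IndexConfig(
        indicators=(
            IndicatorSpec("a1", "pa", "positive"),
            IndicatorSpec("a2", "pa", "negative"),
            IndicatorSpec("b1", "pb", "positive"),
        )
    )


def random_panel(rng, n_units=10, indicators=("x1", "x2", "x3", "x4")):
    data = rng.uniform(0.0, 1.0, size=(n_units, len(indicators)))
    ids = [f"U{i:02d}" for i in range(n_units)]
    return pd.DataFrame(data, index=ids, columns=list(indicators))


@pytest.fixture
def rng():
    return np.random.default_rng(20211)
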