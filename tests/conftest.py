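import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from etaqsar import DescriptorTable, fixtures

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def named_compounds():
    """Curated named study compounds keyed by compound number."""
    return fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_table(rng, n=12, p=4, prefix="d"):
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"{prefix}{j}" for j in range(p)],
        index=[f"c{i}" for i in range(n)],
    )
    y = pd.Series(rng.normal(size=n), index=X.index, name="pLC50")
    return DescriptorTable(X, y)
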