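import numpy as np
import pandas as pd
import pytest

from soilbeta import CommunityTable, EnvTable, ScenarioConfig


def make_table(counts, sites=None, coords=None, molecule="RNA"):
    """Build a CommunityTable from a plain counts array."""
    counts = np.asarray(counts)
    n = counts.shape[0]
    ids = [f"s{i:02d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "site": sites if sites is not None else ["siteA"] * n,
            "molecule": molecule,
            "x": coords[:, 0] if coords is not None else np.arange(n, dtype=float),
            "y": coords[:, 1] if coords is not None else np.zeros(n),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    taxa = [f"t{j}" for j in range(counts.shape[1])]
    return CommunityTable(pd.DataFrame(counts, index=ids, columns=taxa), meta)


@pytest.fixture
def toy_table():
    return make_table([[5, 3, 0], [2, 2, 6], [0, 1, 9]])


@pytest.fixture
def toy_env():
    return EnvTable(pd.DataFrame(
        {"pH": [4.0, 6.0, 5.0], "P": [10.0, 30.0, 20.0]},
        index=["s00", "s01", "s02"],
    ))


@pytest.fixture
def desk_config():
    """Desk-scale generator configuration used across simulation tests."""
    return ScenarioConfig.desk(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
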