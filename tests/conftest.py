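import numpy as np
import pandas as pd
import pytest

from habqual.synth import ScenarioConfig, gen_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def inventory_csv(tmp_path):
    """Write a small inventory CSV; returns (path, frame-as-written)."""

    def _write(rows, columns=("tree_id", "concession_id", "lon", "lat", "dbh", "latas"),
               name="inv.csv", sep=","):
        df = pd.DataFrame(rows, columns=list(columns))
        path = tmp_path / name
        df.to_csv(path, index=False, sep=sep)
        return path, df

    return _write


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic world under the reference study conditions."""
    return gen_dataset(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced world for fast pipeline tests (~1/4 of the extent)."""
    return ScenarioConfig(
        seed=3,
        extent=(-69.80, -12.80, -69.68, -12.68),
        n_concessions=4,
    )
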