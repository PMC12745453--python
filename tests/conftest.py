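import numpy as np
import pandas as pd
import pytest

from parkscape import FEATURES, GeneratorConfig, default_met_table, default_taxonomy
from parkscape.behavior import BehaviorRecord


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def met():
    return default_met_table()


@pytest.fixture
def rng():
    return np.random.default_rng(4242)


def make_record(code, count, plot_id="p1", **kw):
    return BehaviorRecord(plot_id=plot_id, session="weekday-08:00-10:00",
                          code=code, count=count, **kw)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_cfg():
    return GeneratorConfig(seed=11, n_plots=20, n_images=80)


def random_profiles_frame(rng, n, plot_prefix="p"):
    """Random feasible profile table: independent U(0, 0.12) fractions."""
    data = {"plot_id": [f"{plot_prefix}{i}" for i in range(n)]}
    for f in FEATURES:
        data[f] = rng.uniform(0, 0.12, n)
    data["n_images"] = 36
    return pd.DataFrame(data)


@pytest.fixture
def profiles_frame_factory():
    return random_profiles_frame
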