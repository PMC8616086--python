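import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """Three genes, two libraries; only g1 clears the >=2-everywhere filter."""
    return pd.DataFrame(
        {"lib1": [2, 5, 0], "lib2": [2, 1, 0]},
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )


@pytest.fixture
def small_sim_config():
    """A fast, fully-featured synthetic study for integration tests."""
    from mirtriad import SimConfig

    return SimConfig(
        n_genes=300,
        n_targets=15,
        library_size=300_000,
        nb_dispersion=0.05,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
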