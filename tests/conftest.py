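import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ssvep_tuning as st

settings.register_profile(
    "ci", max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def li_weights():
    return st.contrast_weights("lateral_inhibition")


@pytest.fixture(scope="session")
def small_montage():
    return st.make_montage(n_channels=24, cluster_size=4)


@pytest.fixture(scope="session")
def full_montage():
    return st.make_montage(n_channels=129, cluster_size=8)


@pytest.fixture(scope="session")
def profiles40():
    return st.sample_subjects(40, seed=11)


@pytest.fixture(scope="session")
def gen_table40(profiles40, li_weights):
    """Generalization-phase SNR table with a planted lateral-inhibition pattern."""
    return st.simulate_snr_table(
        profiles40, pattern=li_weights, include_phases=("generalization",), seed=12
    )


@pytest.fixture(scope="session")
def fixture_table_6x6(li_weights):
    """Tiny deterministic 6-subject x 6-condition table for oracle comparisons."""
    profs = st.sample_subjects(6, seed=10)
    return st.simulate_snr_table(
        profs, pattern=li_weights, include_phases=("generalization",), seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_epochs(data: np.ndarray, fs: float = 250.0, t0_ms: float = -600.0,
                conditions=None, phases=None) -> st.EpochSet:
    n = data.shape[0]
    meta = pd.DataFrame({
        "phase": phases if phases is not None else ["generalization"] * n,
        "condition": conditions if conditions is not None else ["CS+"] * n,
        "reinforced": [False] * n,
    })
    channels = [f"E{i + 1}" for i in range(data.shape[1])]
    return st.EpochSet(data, fs, t0_ms, meta, channels)
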