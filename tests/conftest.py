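import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("repro", derandomize=True)
hypothesis_settings.load_profile("repro")

from netpharm import io as npio
from netpharm.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def candidate_records():
    """The bundled 32-compound reference ADMET table."""
    return npio.load_candidate_table()


@pytest.fixture(scope="session")
def published_scores():
    """Printed composite scores from the bundled reference table."""
    import pandas as pd

    df = pd.read_csv(npio.candidate_table_path())
    return dict(zip(df["compound_id"], df["published_score"]))


@pytest.fixture
def small_sim_config():
    """Down-scaled simulation settings for fast unit tests."""
    return SimulationConfig(seed=11, n_library=100, pass_fraction=0.4,
                            n_compounds=20, n_targets=30, hub_count=5,
                            n_events=2000, n_diseases=15, n_groups=6)
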