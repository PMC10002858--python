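import numpy as np
import pytest

from memprobe.synthetic import (
    SyntheticParams,
    ContactPlan,
    simulate_trajectory,
    worked_fixtures,
    fixture_selections,
)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Hand-written worked-example PDB fixtures, written once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return worked_fixtures(out)


@pytest.fixture(scope="session")
def fixture_spec():
    return fixture_selections()


@pytest.fixture(scope="session")
def small_traj():
    """A modest synthetic trajectory with one planted PS contact."""
    params = SyntheticParams(
        n_frames=500,
        seed=42,
        contact_plan=[ContactPlan("K271", "PS", 0.5, 20.0)],
    )
    return simulate_trajectory(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
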