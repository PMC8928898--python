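import pytest

from beetrack.core import AnalysisConfig
from beetrack.pipeline import analyze_stream
from beetrack.simulator import NoiseModel, SimScenario, simulate_session


@pytest.fixture()
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_session():
    """A short crossing-free session with a handful of bees, no noise."""
    scenario = SimScenario(
        n_bees=6,
        duration_s=600.0,
        rng_seed=11,
        initial_inside_range_s=(10.0, 120.0),
    )
    truth, stream = simulate_session(scenario)
    return scenario, truth, stream


@pytest.fixture(scope="session")
def recovery_session():
    """The full-roster benchmark: 24 bees, 12x10 grid, 30 simulated minutes,
    noise-free, crossing-free."""
    scenario = SimScenario(n_bees=24, grid_rows=12, grid_cols=10,
                           duration_s=1800.0, rng_seed=7)
    truth, stream = simulate_session(scenario)
    return scenario, truth, stream


@pytest.fixture(scope="session")
def recovery_bundle(recovery_session):
    scenario, truth, stream = recovery_session
    return analyze_stream(stream, AnalysisConfig())
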