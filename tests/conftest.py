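import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popassembly.events import DetectionConfig, detect_population_events
from popassembly.synthetic import SimulationConfig, make_protocol, simulate_raster

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


SMALL_LAYOUT = (("spont", 120.0), ("stim", 120.0), ("spont", 120.0))


@pytest.fixture(scope="session")
def awake_session():
    """A small awake-mode session with detected events, shared across tests."""
    protocol = make_protocol(8, 6, 0.5, 1.0, 30.0, SMALL_LAYOUT, rng=7)
    cfg = SimulationConfig(n_neurons=150, mode="awake", seed=21)
    raster, truth = simulate_raster(cfg, protocol)
    events, rate = detect_population_events(raster, DetectionConfig(seed=22))
    return {"protocol": protocol, "cfg": cfg, "raster": raster,
            "truth": truth, "events": events, "rate": rate}
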