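import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fretkit

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def static_run():
    """A short realistic static measurement run through the full pipeline,
    shared by tests that only need *some* bursts to poke at."""
    model = fretkit.TwoStateModel(seed=42)
    stream = fretkit.simulate_photon_stream(model, 30.0)
    bg = fretkit.estimate_background(stream)
    bursts = fretkit.search_bursts(stream, bg)
    metrics = fretkit.filter_bursts(
        fretkit.compute_metrics(stream, bursts, bg, model.corrections))
    return {"model": model, "stream": stream, "bg": bg,
            "bursts": bursts, "metrics": metrics}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
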