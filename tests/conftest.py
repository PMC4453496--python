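import numpy as np
import pytest
from hypothesis import settings

from grsgrowth import SimulationConfig, simulate_cohort
from grsgrowth.simulate import OffspringSpec, ScheduleSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def small_config(seed=42, **kw):
    defaults = dict(
        n_families=60,
        offspring=OffspringSpec(mean=3.0, min=1, max=6),
        schedule=ScheduleSpec(dense_n=8, sparse_interval=4.0, max_age=50.0),
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by read-only tests."""
    return simulate_cohort(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
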