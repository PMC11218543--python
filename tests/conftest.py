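import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_rr(rng: np.random.Generator, n: int, mean: float = 900.0, sd: float = 60.0):
    """An i.i.d. Normal RR draw clipped away from zero; diffs straddle 50 ms."""
    return np.clip(rng.normal(mean, sd, size=n), 350.0, 1900.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


@pytest.fixture
def long_rr(rng):
    """~5 min of plausible RR intervals (defined frequency features)."""
    from hrvfatigue.containers import RRSeries

    return RRSeries(random_rr(rng, 340, mean=880.0, sd=45.0))


@pytest.fixture
def ipfm_rr():
    """Deterministic IPFM fixture with mixed-band modulation."""
    from hrvfatigue.simulate import ModulationSpec, generate_rr_ipfm

    return generate_rr_ipfm(
        ModulationSpec(mean_rr=850.0, amp_vlf=0.01, amp_lf=0.05, amp_hf=0.04, seed=11)
    )
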