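import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pursuitval import ForgoWorld, OutsideContext, Pursuit, generate_random_world

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def demo_pursuit_context():
    """Reference pursuit-in-context: reward 4 over 4 time units, outside 0.7 over 3."""
    return Pursuit(4.0, 4.0), OutsideContext(0.7, 3.0)


@pytest.fixture
def ss_ll_short():
    """SS 2.5/2.5 vs LL 5/8.5 with a 6-unit outside (policy-transition example)."""
    return Pursuit(2.5, 2.5, "SS"), Pursuit(5.0, 8.5, "LL"), 6.0


@pytest.fixture
def ss_ll_misest():
    """SS 2/2.5 vs LL 4.75/8 with a 10-unit outside (misestimation-map example)."""
    return Pursuit(2.0, 2.5, "SS"), Pursuit(4.75, 8.0, "LL"), 10.0


@pytest.fixture
def ss_ll_delay():
    """SS 2/3 vs LL 5/12.6, outside rate 0.5 over 5 (delay-effect example)."""
    return (
        Pursuit(2.0, 3.0, "SS"),
        Pursuit(5.0, 12.6, "LL"),
        OutsideContext.from_rate(0.5, 5.0),
    )


@pytest.fixture
def two_pursuit_world():
    """Two pursuits whose joint acceptance yields a global rate of exactly 1."""
    return ForgoWorld(
        (Pursuit(2.0, 1.0, "a"), Pursuit(4.0, 2.0, "b")), (0.5, 0.25), 0.0
    )


def random_pursuit_context(rng: np.random.Generator):
    """One random valid (pursuit, outside) pair with mixed-sign rewards."""
    return (
        Pursuit(float(rng.uniform(-5, 10)), float(rng.uniform(0.1, 10))),
        OutsideContext(float(rng.uniform(-5, 10)), float(rng.uniform(0.1, 10))),
    )


@pytest.fixture
def random_worlds():
    """Factory: ``random_worlds(count, max_n, seed)`` -> list of ForgoWorld."""

    def make(count: int, max_n: int, seed: int):
        rng = np.random.default_rng(seed)
        return [
            generate_random_world(int(rng.integers(1, max_n + 1)), int(rng.integers(2**31)))
            for _ in range(count)
        ]

    return make
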