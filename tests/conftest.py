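import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from commrobust import ObservationStream, make_population, simulate_stream

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def four_group_stream() -> ObservationStream:
    """The classic simple-ratio worked example: {A,B},{A,B},{A},{B}."""
    return ObservationStream(
        [{"A", "B"}, {"A", "B"}, {"A"}, {"B"}], ["A", "B", "C"], "group"
    )


def make_two_clique_stream(n_groups: int = 50) -> ObservationStream:
    """Two cliques always observed as complete, disjoint groups.

    Perfectly separable: SRI = 1 within cliques, 0 between, so community
    detection recovers the cliques from any resample that contains both.
    """
    cliques = [frozenset({"A", "B", "C"}), frozenset({"D", "E", "F"})]
    units = [cliques[t % 2] for t in range(n_groups)]
    return ObservationStream(units, ["A", "B", "C", "D", "E", "F"], "group")


@pytest.fixture
def two_clique_stream() -> ObservationStream:
    return make_two_clique_stream(50)


def simulated_stream(p_w, p_obs, n=40, c=4, n_periods=100, seed=0):
    rng = np.random.default_rng(seed)
    pop = make_population(n, c, p_w, p_obs, rng=rng)
    return simulate_stream(pop, n_periods=n_periods, rng=rng)
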