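import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dynastab import csp_inference as ci
from dynastab.data_model_io import DiscreteProfile, SteadyStateConstraintSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def triangle_problem():
    """3-node triangle skeleton constrained by the profiles (1,1,1) and (2,2,2)."""
    sk = ci.build_skeleton([("A", "B"), ("B", "C"), ("A", "C")])
    cons = SteadyStateConstraintSet(
        [DiscreteProfile("ABC", [1, 1, 1]), DiscreteProfile("ABC", [2, 2, 2])]
    )
    return ci.encode(sk, cons)


@pytest.fixture(scope="session")
def triangle_solutions(triangle_problem):
    return ci.enumerate_solutions(triangle_problem)


@pytest.fixture(scope="session")
def small_scenario():
    from dynastab import synthetic_fixtures as sf

    return sf.generate_scenario(n_nodes=6, n_edges=9, n_per_cluster=25, noise_sd=0.05, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
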