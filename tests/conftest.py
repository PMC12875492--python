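import pytest

from netcentral import run_axiom_battery, run_numerical_battery, scorecards


@pytest.fixture(scope="session")
def axiom_matrix():
    """Default axiom battery: connected labeled corpus n <= 5 plus registry."""
    return run_axiom_battery(seed=0)


@pytest.fixture(scope="session")
def benchmark_matrix():
    """Default numerical battery: six families on the {5..200} grid."""
    return run_numerical_battery()


@pytest.fixture(scope="session")
def equal_weight_cards(axiom_matrix, benchmark_matrix):
    return scorecards(axiom_matrix, benchmark_matrix, 0.5, 0.5)
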