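import pytest

from transrank.task_design import (
    DEFAULT_ITEMS,
    DEFAULT_PAIR_SET,
    RankOrder,
    build_learning_schedule,
    build_test_schedule,
)


@pytest.fixture(scope="session")
def identity_rank() -> RankOrder:
    """A..H at ranks 1..8."""
    return RankOrder(DEFAULT_ITEMS)


@pytest.fixture(scope="session")
def default_learn():
    return build_learning_schedule(DEFAULT_PAIR_SET, 4, seed=101)


@pytest.fixture(scope="session")
def default_test():
    return build_test_schedule(8, 10, seed=102)
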