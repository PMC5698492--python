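import numpy as np
import pytest

from dsfdr import AbundanceMatrix, GroupAssignment
from dsfdr.stats_core import StatisticProfile


@pytest.fixture
def toy_matrix():
    """3 features × 4 samples with mixed tie structure."""
    return AbundanceMatrix(
        [[0, 0, 5, 3], [7, 7, 7, 7], [1, 2, 3, 4]],
        ("sparse", "constant", "dense"),
        ("s1", "s2", "s3", "s4"),
    )


@pytest.fixture
def toy_groups():
    return GroupAssignment([0, 0, 1, 1])


@pytest.fixture
def worked_profile():
    """Two features, four permutations; FDR̂ values known by hand."""
    return StatisticProfile(
        observed=[10.0, 2.0],
        permuted=[[1.0, 2.0, 1.0, 3.0], [2.0, 1.0, 2.0, 1.0]],
        statistic_name="meanrank",
    )


@pytest.fixture
def groups_5_5():
    return GroupAssignment([0] * 5 + [1] * 5)


def random_count_matrix(rng, m, n, high=6):
    """Small random count table; retries until no row is all-equal-free issues."""
    values = rng.integers(0, high, size=(m, n)).astype(float)
    return AbundanceMatrix(
        values,
        tuple(f"f{i}" for i in range(m)),
        tuple(f"s{j}" for j in range(n)),
    )
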