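import numpy as np
import pytest

from evrtest import (
    GroupMoments,
    all_group_moments,
    build_scenario,
    sample_scenario,
)


def gm(label, n, sd_x, sd_y, r, mean_x=0.0, mean_y=0.0):
    """Shorthand for constructing group moments in tests."""
    return GroupMoments(label, n, mean_x, mean_y, sd_x, sd_y, r)


@pytest.fixture(scope="session")
def sem_groups():
    """Moments of one seeded draw from the two-condition example population
    (rho = 0.45 in both conditions, sd_y 2 vs 1, sd_x 1, n = 300 each)."""
    sample = sample_scenario(build_scenario("sem_example"), seed=11)
    groups = all_group_moments(sample)
    by = {g.label: g for g in groups}
    return [by["control"], by["video"]]


@pytest.fixture(scope="session")
def two_group_sample():
    """A seeded categorical draw with genuinely different variance ratios."""
    return sample_scenario(build_scenario("2", 3, sizes=(500, 400)), seed=5)
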