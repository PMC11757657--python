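import numpy as np
import pytest

from pannet_ips import (GraphBuildConfig, SyntheticCohortConfig,
                        build_case_bags, generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A small full cohort shared by pipeline-level tests."""
    cfg = SyntheticCohortConfig(n_cases=12, grid_shape=(12, 12),
                                ips_proportions=(1 / 3, 1 / 3, 1 / 3),
                                seed=11)
    cases, slides = generate_cohort(cfg)
    return cfg, cases, slides


@pytest.fixture(scope="session")
def small_bags(small_cohort):
    cfg, cases, slides = small_cohort
    bags = build_case_bags(cases, slides, GraphBuildConfig(max_hops=2))
    labels = {c.case_id: c.ips_label for c in cases}
    return bags, labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
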