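import pytest

from ccm_dcea import (FixedParams, ethiopia_fixture, run_cohort,
                      region_schedule, synthetic_reference_set)


@pytest.fixture(scope="session")
def ethiopia():
    """(RegionTable, FixedParams, published cost table)."""
    return ethiopia_fixture()


@pytest.fixture(scope="session")
def regions(ethiopia):
    return ethiopia[0]


@pytest.fixture(scope="session")
def params():
    return FixedParams()


@pytest.fixture(scope="session")
def cost_table(ethiopia):
    return ethiopia[2]


@pytest.fixture(scope="session")
def reference_set():
    return synthetic_reference_set()


@pytest.fixture(scope="session")
def cohort_arms(regions, params, reference_set):
    """Per-region (baseline, target) cohort runs, computed once."""
    arms = {}
    for region in regions:
        schedule = region_schedule(region, reference_set)
        arms[region.name] = (
            run_cohort(schedule, region, params, region.baseline_coverage),
            run_cohort(schedule, region, params, params.target_coverage),
        )
    return arms
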