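"""Shared fixtures: reduced-scale study runs reused across acceptance tests.

The replication grids are expensive, so each is computed once per session.
Seeds are fixed constants so every run of the suite sees the same data.
"""

import pytest

from raschld import StudyConfig, run_study


@pytest.fixture(scope="session")
def td_records_r50():
    """All 18 trait-dependence cells at 50 replications each."""
    return run_study(StudyConfig(ld_types=("TD",), n_replications=50, base_seed=1))


@pytest.fixture(scope="session")
def rd_records_r50():
    """All 18 response-dependence cells at 50 replications each."""
    return run_study(StudyConfig(ld_types=("RD",), n_replications=50, base_seed=2))


@pytest.fixture(scope="session")
def td_c1_records_r100():
    """TD c=1 cells (both lengths, all sample sizes) at 100 replications."""
    return run_study(
        StudyConfig(ld_types=("TD",), magnitudes=(1.0,), n_replications=100, base_seed=3)
    )


@pytest.fixture(scope="session")
def td_c2_records_r100():
    """TD c=2 cells at 100 replications."""
    return run_study(
        StudyConfig(ld_types=("TD",), magnitudes=(2.0,), n_replications=100, base_seed=4)
    )


@pytest.fixture(scope="session")
def td_c0_records_r100():
    """TD c=0 cells at 100 replications (null-model recovery baselines)."""
    return run_study(
        StudyConfig(ld_types=("TD",), magnitudes=(0.0,), n_replications=100, base_seed=5)
    )


@pytest.fixture(scope="session")
def rd_d_records_r100():
    """RD d in {0,1,2} at I=30, N=250, 100 replications per magnitude."""
    return run_study(
        StudyConfig(
            ld_types=("RD",), n_items=(30,), n_persons=(250,),
            n_replications=100, base_seed=6,
        )
    )
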