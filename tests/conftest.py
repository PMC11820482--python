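import pandas as pd
import pytest

from wbq.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A fully observed synthetic cohort reused across read/score tests."""
    return generate_cohort(CohortSpec(n=60, seed=42)).responses


@pytest.fixture(scope="session")
def scored_small(small_cohort) -> pd.DataFrame:
    from wbq.scoring import score_table

    return score_table(small_cohort)
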