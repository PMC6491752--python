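import numpy as np
import pandas as pd
import pytest

import sdindex as sd


@pytest.fixture(scope="session")
def strong_cohort() -> sd.SyntheticCohort:
    """Default strong-effect synthetic training cohort (104 + 90)."""
    return sd.generate_cohort(sd.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def fitted(strong_cohort) -> sd.SDIResults:
    model = sd.StrokeDysbiosisIndex(strong_cohort.table, strong_cohort.clinical["group"])
    return model.fit(seed=11)


@pytest.fixture()
def toy_table() -> sd.AbundanceTable:
    df = pd.DataFrame(
        [[30, 10, 0], [5, 20, 5], [12, 8, 4]],
        index=["s1", "s2", "s3"],
        columns=["GenA", "GenB", "GenC"],
    )
    return sd.AbundanceTable(df)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
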