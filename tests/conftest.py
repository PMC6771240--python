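import numpy as np
import pandas as pd
import pytest

from ascsig import SyntheticConfig, generate_cohort, associate_all
from ascsig.core_data import AbundanceMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """Ascites-only cohort with 3 adverse + 3 favorable planted markers."""
    cfg = SyntheticConfig(
        n_patients=80,
        n_proteins=40,
        n_adverse=3,
        n_favorable=3,
        effect_log_hr=np.log(8),
        n_oc_plasma=0,
        n_n_plasma=0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_association(small_cohort):
    cohort, _ = small_cohort
    return associate_all(cohort)


@pytest.fixture(scope="session")
def mixed_matrix():
    """Tiny abundance matrix with all three sample classes."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.uniform(10, 1000, (9, 5)),
        index=[f"S{i}" for i in range(9)],
        columns=[f"P{i}" for i in range(5)],
    )
    classes = pd.Series(
        ["ascites"] * 4 + ["oc_plasma"] * 3 + ["n_plasma"] * 2, index=values.index
    )
    return AbundanceMatrix(values, classes)
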