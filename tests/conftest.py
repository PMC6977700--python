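import numpy as np
import pandas as pd
import pytest

from ceradys import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-size two-state cohort: 46/73 samples, 20 planted triplets."""
    return generate_cohort(CohortParams(seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted signal at all (delta=0, no decoupling)."""
    return generate_cohort(
        CohortParams(
            n_mrna=300, n_lncrna=150, n_mirna=100,
            n_planted=0, n_dysregulated=0, delta=0.0,
            n_decoy_interactions=0, seed=11,
        )
    )


@pytest.fixture
def tiny_expression():
    df = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    from ceradys import ExpressionMatrix

    return ExpressionMatrix(df, "mRNA")
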