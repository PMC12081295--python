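import numpy as np
import pandas as pd
import pytest

import lewyprog as lp


@pytest.fixture
def small_matrix():
    """Three complete 16-region ordinal cases with metadata."""
    rng = np.random.default_rng(7)
    scores = pd.DataFrame(
        rng.integers(0, 5, size=(3, 16)),
        index=pd.Index(["a", "b", "c"], name="case_id"),
        columns=list(lp.REGIONS),
    )
    scores.iloc[0, 0] = 1  # ensure every case is Lewy-positive
    metadata = pd.DataFrame(
        {"diagnosis": ["ILBD", "PD", "PDD_DLB"],
         "ad_flag": [False, True, False],
         "age": [81.0, 77.0, np.nan]},
        index=scores.index,
    )
    return lp.PathologyMatrix(scores=scores, metadata=metadata)


@pytest.fixture(scope="session")
def cohort300():
    """The default 3-subtype synthetic cohort used by recovery tests."""
    spec = lp.CohortSpec(n_cases=300, seed=0)
    matrix, truth = lp.make_cohort(spec)
    return spec, matrix, truth
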