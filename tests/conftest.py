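import numpy as np
import pandas as pd
import pytest

import specurve as sc
from specurve.preprocess import score_scales, standardize
from specurve.simulate import CONTENT_COLUMNS, COVARIATE_COLUMNS, OUTCOME_COLUMNS


def prepare(data: pd.DataFrame) -> pd.DataFrame:
    """Score the scales and standardize all analysis columns."""
    out = score_scales(data)
    return standardize(out, OUTCOME_COLUMNS + CONTENT_COLUMNS + COVARIATE_COLUMNS)


@pytest.fixture(scope="session")
def null_survey():
    """Complete all-effects-zero survey, scored and standardized (n=400)."""
    cfg = sc.build_default_config(n_participants=400)
    return prepare(sc.generate_survey(cfg, seed=11))


@pytest.fixture(scope="session")
def null_survey_large():
    """Larger null survey for Monte-Carlo-style checks (n=10,000)."""
    cfg = sc.build_default_config(n_participants=10_000)
    return sc.generate_survey(cfg, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
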