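import pandas as pd
import pytest

from ponsmrsi.config import CohortConfig
from ponsmrsi.metrics import add_composition, qc_filter
from ponsmrsi.ratios import build_ratio_table
from ponsmrsi.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config) -> pd.DataFrame:
    frame, _ = simulate_cohort(default_config)
    return frame


@pytest.fixture(scope="session")
def cohort_truth(default_config):
    return simulate_cohort(default_config)[1]


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    """No measurement noise, no group effects, no CRLB inflation."""
    return CohortConfig(
        seed=7, noise_sd=0.0, effect_map=(), crlb_model={"inflate_prob": 0.0}
    )


@pytest.fixture(scope="session")
def noiseless_ratio_table(noiseless_config) -> pd.DataFrame:
    frame, _ = simulate_cohort(noiseless_config)
    corrected, _ = qc_filter(add_composition(frame))
    return build_ratio_table(corrected)


@pytest.fixture(scope="session")
def ratio_table(cohort) -> pd.DataFrame:
    corrected, _ = qc_filter(add_composition(cohort))
    return build_ratio_table(corrected)
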