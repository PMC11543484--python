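import numpy as np
import pandas as pd
import pytest

from eldltg import CohortSpec, HazardSpec, generate_cohort


@pytest.fixture(scope="session")
def small_panels() -> pd.DataFrame:
    """A handful of hand-sized lipid panels covering normal, degenerate
    and out-of-range inputs (mg/dl)."""
    return pd.DataFrame(
        {
            "tc": [200.0, 265.0, 150.0, np.nan, 50.0],
            "tg": [150.0, 186.0, 1200.0, 100.0, 80.0],
            "hdl_c": [50.0, 54.5, 35.0, 40.0, 50.0],
        }
    )


@pytest.fixture(scope="session")
def survival_cohort() -> pd.DataFrame:
    """One synthetic cohort with an eLDL-TG-driven hazard, reused by
    survival tests (session-scoped for speed)."""
    spec = CohortSpec(n=4000, seed=7, hazard=HazardSpec(hr_per_sd=1.4))
    return generate_cohort(spec)
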