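import numpy as np
import pandas as pd
import pytest

import brainage_delta as bd


@pytest.fixture(scope="session")
def cohort400() -> bd.Cohort:
    """Mid-size cohort with a quarter obese; shared read-only fixture."""
    return bd.generate_cohort(400, 0.25, seed=42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_cohort_table(ages, bmi_classes, sexes=None, education=None) -> pd.DataFrame:
    """Hand-built participant table for construction-level tests."""
    n = len(ages)
    sexes = sexes or ["female"] * n
    education = education or [3] * n
    bmi = {"normal": 22.0, "overweight": 27.0, "obese": 32.0}
    return pd.DataFrame(
        {
            "id": [f"p{i:03d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "education": education,
            "bmi": [bmi[c] for c in bmi_classes],
            "bmi_class": bmi_classes,
            "mmse": [28] * n,
        }
    )
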