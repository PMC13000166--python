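import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from organscale.cohort_io import CohortTable  # noqa: E402


@pytest.fixture
def tiny_cohort_df() -> pd.DataFrame:
    """Three well-formed animals; the third lacks a tibia length."""
    return pd.DataFrame(
        {
            "animal_id": ["m1", "m2", "m3"],
            "sex": ["female", "female", "male"],
            "age_group": ["EA", "EA", "LA"],
            "heart_weight_mg": [110.0, 120.5, 171.25],
            "body_weight_g": [22.0, 24.5, 45.0],
            "tibia_length_mm": [18.1, 18.5, np.nan],
            "centre": ["A", "A", None],
        }
    )


@pytest.fixture
def tiny_cohort(tiny_cohort_df) -> CohortTable:
    return CohortTable(tiny_cohort_df, provenance="fixture")


@pytest.fixture
def tiny_cohort_csv(tmp_path, tiny_cohort_df):
    path = tmp_path / "cohort.csv"
    df = tiny_cohort_df.copy()
    df["centre"] = df["centre"].fillna("")
    df.to_csv(path, index=False, na_rep="")
    return path
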