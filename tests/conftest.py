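import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from maihda import default_design

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture()
def toy_records():
    """Ten hand-built records: 2 under 21, 1 'other' race, 1 missing education."""
    rows = []
    for i in range(10):
        rows.append(
            {
                "sex": "Men" if i % 2 == 0 else "Women",
                "race_ethnicity": "White",
                "age_group": "25-59",
                "education": "Some college",
                "age_years": 40,
                "survey_year": 2005,
                "drinker": 1,
                "gpd": 5.0,
            }
        )
    rows[0]["age_years"] = 18
    rows[1]["age_years"] = 20
    rows[2]["race_ethnicity"] = "other"
    rows[3]["education"] = None
    return pd.DataFrame(rows)


@pytest.fixture()
def drinker_toy_records():
    """Ten drinker-analysis inputs: 3 non-drinkers, 1 drinker missing gpd."""
    rows = []
    for i in range(10):
        rows.append(
            {
                "sex": "Women",
                "race_ethnicity": "Black",
                "age_group": "60+",
                "education": "High school or less",
                "survey_year": 2010,
                "drinker": 1,
                "gpd": 3.0,
            }
        )
    for i in (0, 4, 7):
        rows[i]["drinker"] = 0
        rows[i]["gpd"] = np.nan
    rows[2]["gpd"] = np.nan
    return pd.DataFrame(rows)
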