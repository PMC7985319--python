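import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import zincgeo as zg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: Compact window (~440 km square) used for spatial Monte-Carlo studies:
#: dense enough that lag bins inside the correlation range hold many pairs.
DENSE_WINDOW = {"lon_window": (37.0, 41.0), "lat_window": (6.0, 10.0)}

#: Generating variogram used throughout the spatial tests.
TRUE_MODEL = zg.VariogramModel(c0=27.0, c1=39.62, a=14.79)


def field_frame(z, locs):
    """Wrap simulated field values as EA aggregates for the spatial API."""
    return pd.DataFrame(
        {
            "ea_id": [f"EA{i}" for i in range(len(z))],
            "mean_zn": z,
            "mean_lon": locs[:, 0],
            "mean_lat": locs[:, 1],
            "n_records": 1,
        }
    )


@pytest.fixture(scope="session")
def small_survey():
    """A complete synthetic survey (~40 EAs) shared across read-only tests."""
    cfg = zg.SimulationConfig(seed=42, n_ea=40, **DENSE_WINDOW)
    df, truth = zg.simulate_survey(cfg)
    return df, truth, cfg


@pytest.fixture(scope="session")
def working_table(small_survey):
    """Excluded, staged and BRINDA-adjusted working table."""
    df, _, _ = small_survey
    retained, report = zg.apply_exclusions(df)
    retained = zg.stage_inflammation_frame(retained)
    fit = zg.fit_brinda(retained)
    return zg.adjust_frame(retained, fit), fit, report


def survey_row(**over):
    """One fully populated survey record, overridable per test."""
    base = {
        "id": "P0", "ea_id": "EA0", "lon": 39.0, "lat": 8.0,
        "region": "Oromia", "residence": "rural", "group": "WRA",
        "age": 30.0, "sex": "female", "draw_time": "morning",
        "fasting": False, "zn": 60.0, "crp": 1.0, "agp": 0.8,
        "weight": 1.0, "head_educated": True, "diarrhea": False,
        "analytical_outlier": False,
    }
    base.update(over)
    return base


@pytest.fixture(scope="session")
def attrition_survey():
    """A 3373-record survey with disjoint missingness groups.

    101 records lack GPS, 172 lack meal context, 30 lack an inflammation
    marker, 4 lack socio-demographics and 2 are flagged analytical
    outliers, leaving 3064 complete records.
    """
    rows = []
    i = 0

    def add(n, **over):
        nonlocal i
        for _ in range(n):
            rows.append(survey_row(id=f"P{i:05d}", ea_id=f"EA{i % 300:04d}", **over))
            i += 1

    add(101, lon=np.nan, lat=np.nan)
    add(172, draw_time=np.nan)
    add(30, crp=np.nan)
    add(4, head_educated=np.nan)
    add(2, analytical_outlier=True)
    add(3373 - 309)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def table1_survey():
    """3064 complete records with the reference demographic composition.

    519 young children, 962 school-age children, 402 men and 1181 women of
    reproductive age; 2296 rural; inflammation stages 2123 none /
    70 incubation / 262 early / 609 late convalescence.
    """
    rows = []
    i = 0
    stage_markers = {
        "none": dict(crp=1.0, agp=0.8),
        "incubation": dict(crp=8.0, agp=0.9),
        "early_convalescence": dict(crp=8.0, agp=1.4),
        "late_convalescence": dict(crp=1.0, agp=1.4),
    }
    stage_pool = (
        ["none"] * 2123 + ["incubation"] * 70
        + ["early_convalescence"] * 262 + ["late_convalescence"] * 609
    )
    group_pool = ["YC"] * 519 + ["SAC"] * 962 + ["MEN"] * 402 + ["WRA"] * 1181
    residence_pool = ["rural"] * 2296 + ["urban"] * 768
    rng = np.random.default_rng(0)
    for grp, res, stg in zip(group_pool, residence_pool, stage_pool):
        age = {"YC": 3.0, "SAC": 9.0, "MEN": 30.0, "WRA": 30.0}[grp]
        sex = {"MEN": "male", "WRA": "female"}.get(grp, "female")
        rows.append(
            survey_row(
                id=f"P{i:05d}", group=grp, residence=res, age=age, sex=sex,
                zn=float(rng.normal(57.0, 8.0)), weight=float(rng.lognormal(0, 0.2)),
                **stage_markers[stg],
            )
        )
        i += 1
    return pd.DataFrame(rows)
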