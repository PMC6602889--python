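"""Reference cohort data for whole-body vitamin A kinetics.

Subject characteristics and population-level model estimates from a published
52-day oral [2H8]retinol tracer study in well-nourished older adults: 7 US
and 6 Chinese participants whose serum tracer kinetics were identifiable from
20 d onwards.  Serum retinol concentrations are the means of the 19 samples
collected between 3 h and 52 d; liver weights were estimated as body surface
area x 772 g/m^2.

These values serve as inputs for worked examples, for calibrating the
synthetic-data templates, and for the group-summary pipeline.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_cohort",
    "POPULATION_ESTIMATES",
    "RDA_INTAKE_UMOL_PER_DAY",
]

#: Mean RDA for vitamin A in adults, µmol/d (800 µg retinol activity equiv.).
RDA_INTAKE_UMOL_PER_DAY = 2.8

_COHORT_ROWS = [
    # id, sex, age_y, body_weight_kg, bmi, mean_serum_retinol, liver_weight_g
    ("US1", "M", 47, 72.6, 29.3, 2.34, 1375.0),
    ("US2", "F", 55, 57.7, 25.7, 1.64, 1196.0),
    ("US3", "F", 44, 82.3, 30.7, 1.44, 1494.0),
    ("US4", "F", 70, 54.5, 22.0, 1.41, 1192.0),
    ("US5", "F", 57, 60.4, 27.9, 2.06, 1213.0),
    ("US6", "M", 68, 79.5, 25.9, 1.41, 1519.0),
    ("US7", "F", 67, 65.8, 26.6, 1.85, 1309.0),
    ("CH1", "M", 50, 59.8, 23.9, 1.40, 1251.0),
    ("CH2", "M", 60, 63.8, 21.6, 1.35, 1347.0),
    ("CH3", "F", 57, 77.0, 28.6, 1.10, 1446.0),
    ("CH4", "F", 51, 56.9, 23.7, 0.932, 1208.0),
    ("CH5", "F", 55, 77.4, 29.9, 0.850, 1436.0),
    ("CH6", "M", 53, 72.0, 30.0, 1.58, 1359.0),
]


def load_cohort() -> pd.DataFrame:
    """Subject covariates of the reference US/Chinese cohort (13 rows).

    Columns: id, group ('US'/'Chinese'), sex, age_y, body_weight_kg,
    bmi_kg_m2, mean_serum_retinol_umol_l, liver_weight_g.
    """
    df = pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "id", "sex", "age_y", "body_weight_kg", "bmi_kg_m2",
            "mean_serum_retinol_umol_l", "liver_weight_g",
        ],
    )
    df.insert(1, "group", df["id"].str.startswith("US").map({True: "US", False: "Chinese"}))
    return df


#: Published population-level steady-state estimates (geometric-mean plasma
#: pool in a steady-state solution of the fitted population kinetics), by
#: group and model treatment.  Units: U1/DR µmol/d, masses µmol, days d,
#: liver µmol/g.  Used as worked-example inputs, not recomputed here.
POPULATION_ESTIMATES: dict[str, dict[str, dict[str, float]]] = {
    "US": {
        "1EV":    {"U1": 16.2, "M5": 5.0, "M6": 783.0, "M7": 0.0,
                   "TBS": 783.0, "DR": 12.2, "days_of_stores": 64.4,
                   "liver_va": 0.533},
        "2EV":    {"U1": 14.4, "M5": 5.0, "M6": 926.0, "M7": 29.7,
                   "TBS": 956.0, "DR": 10.8, "days_of_stores": 88.5,
                   "liver_va": 0.65},
        "2EV_DI": {"U1": 2.79, "M5": 5.0, "M6": 1926.0, "M7": 130.0,
                   "TBS": 2056.0, "DR": 2.1, "days_of_stores": 981.0,
                   "liver_va": 1.4},
    },
    "Chinese": {
        "1EV":    {"U1": 6.84, "M5": 3.43, "M6": 219.0, "M7": 0.0,
                   "TBS": 219.0, "DR": 5.13, "days_of_stores": 42.8,
                   "liver_va": 0.148},
        "2EV":    {"U1": 5.86, "M5": 3.43, "M6": 297.0, "M7": 19.6,
                   "TBS": 317.0, "DR": 4.39, "days_of_stores": 72.1,
                   "liver_va": 0.213},
        "2EV_DI": {"U1": 2.94, "M5": 3.43, "M6": 564.0, "M7": 30.1,
                   "TBS": 594.0, "DR": 2.21, "days_of_stores": 269.0,
                   "liver_va": 0.4},
    },
}
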