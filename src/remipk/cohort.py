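"""Baseline cohort table of the 15-patient VA-ECMO remifentanil study.

The study cohort's individual baseline characteristics (sex, age, weight,
BMI, total protein, remifentanil infusion rate, ECMO indication and duration,
CRRT use) are published per patient and are reproduced here as an in-repo
fixture.  ECMO pump speed and flow were reported only as cohort summaries
(median pump speed 2350 RPM, IQR 2302-2532 RPM), so they are carried as
table-level metadata rather than per-patient columns.

Some patients' infusion-rate entries list a primary value plus a range
(e.g. "0.50 (0.50-0.70)"); the primary value is stored in ``rate`` and the
range bounds in ``rate_min``/``rate_max``.  Cohort summaries use the primary
value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["table1_fixture", "summarize_cohort", "PUMP_SPEED_MEDIAN", "PUMP_SPEED_IQR"]

#: Cohort-level ECMO pump speed summaries, RPM.
PUMP_SPEED_MEDIAN = 2350.0
PUMP_SPEED_IQR = (2302.0, 2532.0)

# patient, sex (F=0/M=1), age y, weight kg, BMI kg/m^2, total protein g/dL,
# rate mg/h (primary, min, max), indication, ECMO duration h, CRRT 0/1
_TABLE1 = [
    (1,  1, 69, 69.6, 26.1, 5.3, 0.50, 0.50, 0.70, "NSTEMI", 250, 1),
    (2,  1, 62, 53.8, 18.6, 5.3, 0.40, None, None, "Ischemic cardiomyopathy", 137, 0),
    (3,  0, 55, 60.6, 22.2, 3.3, 0.14, 0.14, 0.20, "Acute MI", 250, 1),
    (4,  0, 76, 40.8, 18.1, 3.0, 0.30, 0.30, 0.35, "Acute MI", 57, 1),
    (5,  1, 63, 69.0, 23.9, 3.9, 0.25, 0.25, 0.35, "Acute MI", 139, 1),
    (6,  1, 52, 70.0, 24.2, 4.6, 0.35, 0.25, 0.35, "Acute MI", 76, 1),
    (7,  1, 19, 69.9, 24.2, 3.4, 0.35, 0.15, 0.35, "Pulmonary embolism", 96, 0),
    (8,  1, 78, 53.0, 22.9, 4.7, 0.35, None, None, "NSTEMI", 234, 0),
    (9,  0, 73, 54.5, 21.2, 4.2, 0.25, 0.25, 0.35, "NSTEMI", 48, 0),
    (10, 1, 57, 94.0, 31.8, 5.0, 0.35, None, None, "Coronary artery occlusive disease", 312, 0),
    (11, 1, 36, 60.0, 20.5, 5.5, 0.35, 0.15, 0.35, "Myocarditis", 106, 0),
    (12, 0, 47, 65.4, 24.3, 6.2, 0.35, None, None, "STEMI", 143, 1),
    (13, 1, 35, 73.0, 23.8, 5.4, 1.0,  None, None, "Atrial fibrillation, bronchiolitis", 532, 1),
    (14, 0, 57, 57.0, 22.0, 4.4, 0.35, None, None, "Angina pectoris", 168, 1),
    (15, 1, 45, 73.2, 24.2, 5.0, 0.20, None, None, "Acute MI", 257, 1),
]

_COLUMNS = ["patient", "sex", "age", "weight", "bmi", "total_protein",
            "rate", "rate_min", "rate_max", "indication", "ecmo_duration", "crrt"]

_CONTINUOUS = ["age", "weight", "bmi", "total_protein", "rate", "ecmo_duration"]
_CATEGORICAL = ["sex", "crrt"]


def table1_fixture() -> pd.DataFrame:
    """The 15-patient baseline cohort table, one row per patient.

    Pump-speed cohort summaries (the only published form) are attached as
    ``df.attrs['pump_speed_median']`` and ``df.attrs['pump_speed_iqr']``.
    """
    df = pd.DataFrame(_TABLE1, columns=_COLUMNS).set_index("patient")
    df.attrs["pump_speed_median"] = PUMP_SPEED_MEDIAN
    df.attrs["pump_speed_iqr"] = PUMP_SPEED_IQR
    return df


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR per continuous column, counts for categorical columns.

    Quantiles use Hyndman-Fan type-6 order statistics (the (n+1)p rule used
    by SPSS), which reproduces the published cohort IQRs exactly for odd n.
    Returns a frame indexed by column with ``median``, ``q25``, ``q75`` for
    continuous variables and ``count``/``fraction`` of the positive category
    for binary ones.
    """
    if cohort is None or len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    rows = {}
    for col in cohort.columns:
        x = cohort[col]
        if col in _CATEGORICAL or (x.dropna().isin([0, 1]).all() and x.nunique() <= 2):
            n_pos = int(x.sum())
            rows[col] = {"median": np.nan, "q25": np.nan, "q75": np.nan,
                         "count": n_pos, "fraction": n_pos / x.notna().sum()}
        elif pd.api.types.is_numeric_dtype(x):
            vals = x.dropna().to_numpy(float)
            if vals.size == 0:
                continue
            q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75], method="weibull")
            rows[col] = {"median": med, "q25": q25, "q75": q75,
                         "count": np.nan, "fraction": np.nan}
    return pd.DataFrame(rows).T
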