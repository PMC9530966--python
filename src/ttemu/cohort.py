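"""Person-day cohort table: schema, invariant checks and delimited-text IO.

A cohort is a pandas DataFrame in long format, one row per patient-day,
sorted by (patient_id, day), days consecutive from 0 within a patient:

======================= ======================================================
column                  meaning
======================= ======================================================
``patient_id``          integer identifier
``day``                 0-based study day from admission
``age``                 standardised age (baseline, repeated on each row)
``sex``                 1 = male (baseline)
``comorbid``            1 = major comorbidity (baseline)
``severity``            illness-severity score that day (time-varying)
``hypoxia``             1 = severe-hypoxia criteria met that day
``measured``            1 = labs/vitals charted that day
``treat``               1 = corticosteroid exposure that day (A_t)
``death``               1 = died by end of that day (absorbing; last row)
``censor``              1 = discharged / lost to follow-up at end of day
``weight``              optional per-patient frequency weight (default 1)
======================= ======================================================

Death and discharge are terminal: no rows follow either, and they never
both occur on a row (death is adjudicated first within a day).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BASELINE_COLS", "TIMEVARYING_COLS", "REQUIRED_COLS",
    "validate_cohort", "read_cohort", "write_cohort",
]

BASELINE_COLS = ["age", "sex", "comorbid"]
TIMEVARYING_COLS = ["severity", "hypoxia", "measured"]
REQUIRED_COLS = ["patient_id", "day", *BASELINE_COLS, *TIMEVARYING_COLS,
                 "treat", "death", "censor"]


def validate_cohort(df: pd.DataFrame, horizon: int | None = None) -> None:
    """Raise ``ValueError`` if the person-day invariants are violated."""
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("empty cohort")
    key = df[["patient_id", "day"]].to_numpy()
    if not (np.lexsort((key[:, 1], key[:, 0])) == np.arange(len(df))).all():
        raise ValueError("rows not sorted by (patient_id, day)")
    if (df["death"].astype(int) & df["censor"].astype(int)).any():
        raise ValueError("death and censor set on the same row")
    grouped = df.groupby("patient_id", sort=False)
    first_day = grouped["day"].first()
    if (first_day != 0).any():
        raise ValueError("patient days must start at 0")
    diffs = grouped["day"].diff().dropna()
    if (diffs != 1).any():
        raise ValueError("patient days must be consecutive")
    # absorbing states: only the last row of a patient may carry death/censor
    term = df["death"].astype(int) + df["censor"].astype(int)
    cum_after = grouped["day"].transform("max") != df["day"]
    if (term[cum_after.to_numpy()] > 0).any():
        raise ValueError("rows present after death or censoring")
    if horizon is not None and (df["day"] >= horizon).any():
        raise ValueError(f"day beyond horizon {horizon}")


def write_cohort(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_cohort(path: str, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if validate:
        validate_cohort(df)
    return df
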