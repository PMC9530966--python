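"""Deriving the trial's exposure, hypoxia and eligibility from raw records.

The emulated trial defines corticosteroid exposure on a day as receipt of at
least 0.5 mg/kg methylprednisolone-equivalent within some rolling 24-hour
window ending that day, and a severe-hypoxia day as use of high-flow nasal
cannula, venturi mask, or (non)invasive ventilation, or SpO2 below 93% on at
least 6 L/min of oxygen by nasal cannula. Inputs are medication
administration records (hours from admission, drug, mg dose) and
respiratory-support/vitals records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GLUCOCORTICOID_EQUIV_MG", "mpred_equivalent", "derive_daily_exposure",
    "derive_daily_hypoxia", "apply_eligibility",
    "HYPOXIA_MODES", "DOSE_THRESHOLD_MG_PER_KG",
]

#: mg of each drug equipotent to 4 mg methylprednisolone (standard table)
GLUCOCORTICOID_EQUIV_MG = {
    "methylprednisolone": 4.0,
    "prednisone": 5.0,
    "prednisolone": 5.0,
    "hydrocortisone": 20.0,
    "dexamethasone": 0.75,
}

#: daily qualifying dose, methylprednisolone-equivalent per kg body weight
DOSE_THRESHOLD_MG_PER_KG = 0.5

#: respiratory-support modes that qualify as severe hypoxia by themselves
HYPOXIA_MODES = frozenset({"high_flow_nc", "venturi", "niv", "imv"})


def mpred_equivalent(drug: str, dose_mg: float) -> float:
    """Convert a glucocorticoid dose to mg methylprednisolone-equivalent."""
    if drug not in GLUCOCORTICOID_EQUIV_MG:
        raise ValueError(f"unknown corticosteroid {drug!r}")
    if dose_mg <= 0:
        raise ValueError("dose_mg must be positive")
    return float(dose_mg) * 4.0 / GLUCOCORTICOID_EQUIV_MG[drug]


def derive_daily_exposure(records: pd.DataFrame, weight_kg: float,
                          horizon: int) -> np.ndarray:
    """Per-day binary exposure from medication administrations of one patient.

    ``records`` needs columns ``timestamp`` (hours from admission), ``drug``
    and ``dose_mg``. Day ``t`` is flagged exposed when some 24-hour window
    ending within day ``t`` (including its opening boundary) accumulates at
    least 0.5 mg/kg methylprednisolone-equivalent. Windows are evaluated
    event-driven: the rolling sum can only peak at a record time or at the
    day boundary, so only those endpoints are checked.
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    out = np.zeros(horizon, dtype=np.int8)
    if len(records) == 0:
        return out
    ts = records["timestamp"].to_numpy(dtype=float)
    if (ts < 0).any():
        raise ValueError("negative record timestamps")
    dose = np.array([mpred_equivalent(d, m) for d, m in
                     zip(records["drug"], records["dose_mg"])])
    order = np.argsort(ts, kind="stable")
    ts, dose = ts[order], dose[order]
    threshold = DOSE_THRESHOLD_MG_PER_KG * weight_kg

    def window_sum(end: float) -> float:
        inside = (ts > end - 24.0) & (ts <= end)
        return float(dose[inside].sum())

    for day in range(horizon):
        ends = [24.0 * day]
        ends.extend(t for t in ts if 24.0 * day <= t < 24.0 * (day + 1))
        if any(window_sum(e) >= threshold for e in ends):
            out[day] = 1
    return out


def derive_daily_hypoxia(records: pd.DataFrame, horizon: int) -> np.ndarray:
    """Per-day severe-hypoxia indicator from respiratory-support records.

    ``records`` needs ``timestamp`` (hours), ``mode``, ``o2_flow_lpm`` and
    ``spo2_pct``. A day is hypoxic if any record that day shows a qualifying
    support mode, or nasal cannula at >= 6 L/min with SpO2 strictly below 93%.
    Day-level binning cannot separate device initiation from continuation, so
    both qualify.
    """
    out = np.zeros(horizon, dtype=np.int8)
    if len(records) == 0:
        return out
    spo2 = records["spo2_pct"].to_numpy(dtype=float)
    flow = records["o2_flow_lpm"].to_numpy(dtype=float)
    if ((spo2 < 0) | (spo2 > 100)).any() or (flow < 0).any():
        raise ValueError("spo2 must be in [0, 100] and flow non-negative")
    day = np.floor(records["timestamp"].to_numpy(dtype=float) / 24.0).astype(int)
    mode = records["mode"].astype(str).to_numpy()
    qualifies = (np.isin(mode, list(HYPOXIA_MODES))
                 | ((mode == "nasal_cannula") & (flow >= 6.0) & (spo2 < 93.0)))
    for d in day[qualifies]:
        if 0 <= d < horizon:
            out[d] = 1
    return out


def apply_eligibility(patients: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the trial's exclusion criteria to a patient table.

    Requires boolean/0-1 columns ``chronic_steroids`` (chronic corticosteroid
    use before admission) and ``external_transfer`` (transferred in from an
    outside hospital). Returns the eligible patients and a per-reason count
    log. Idempotent: re-applying to the output excludes nobody.
    """
    for col in ("chronic_steroids", "external_transfer"):
        if col not in patients.columns:
            raise ValueError(f"patient table missing eligibility flag {col!r}")
    chronic = patients["chronic_steroids"].astype(bool)
    transfer = patients["external_transfer"].astype(bool)
    log = {
        "screened": int(len(patients)),
        "excluded_chronic_steroids": int(chronic.sum()),
        "excluded_external_transfer": int((transfer & ~chronic).sum()),
    }
    kept = patients.loc[~chronic & ~transfer].copy()
    log["eligible"] = int(len(kept))
    return kept, log
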