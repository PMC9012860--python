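"""Researcher-Defined Duration (RDD) comparator.

The classical fixed-assumption alternative to data-driven durations: the
patient is assumed to consume exactly one dispensed unit per day, so the
duration of a fill equals its dispensed quantity.  Output schema matches
`sessa.estimator.assign_durations` so downstream evaluation is
interchangeable.  Unlike the SEE, the assignment is row-local: one
patient's durations never depend on other patients' data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Cohort


def rdd_durations(cohort: Cohort) -> pd.DataFrame:
    """duration_days = dispensed quantity (one unit per day).

    Raises
    ------
    ValueError
        If any fill lacks a quantity; the error names the fill.
    """
    df = cohort.fills.copy().reset_index(drop=True)
    missing = df["quantity"].isna()
    if missing.any():
        row = df[missing].iloc[0]
        raise ValueError(
            f"fill of patient {row['patient_id']} on day {int(row['day'])} has no quantity; "
            "the one-unit-per-day rule needs dispensed quantities"
        )
    days = df["day"].to_numpy()
    pids = df["patient_id"].to_numpy()
    same = np.r_[pids[1:] == pids[:-1], False]
    gap = np.full(len(df), np.nan)
    gap[:-1][same[:-1]] = (days[1:] - days[:-1])[same[:-1]]

    qty = df["quantity"].astype(float).to_numpy()
    out = df[["patient_id", "day", "drug_code"]].copy()
    out["gap_days"] = gap
    out["cluster_id"] = np.nan
    out["duration_days"] = qty
    out["end_day"] = (days + qty.round().astype(int)).astype(int)
    return out
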