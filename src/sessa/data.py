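"""Core record types and delimited-text I/O for prescription-fill data.

Fill histories arrive as comma-delimited text with one row per dispensing:
``patient_id,fill_date,drug_code[,quantity][,true_duration_days]``.
Internally all dates are integer day offsets from the start of the
observational window (day 0); calendar dates exist only at the I/O
boundary.  The observational window is half-open: fills live on days
``0 .. window_days - 1``.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "fill_date", "drug_code")
OPTIONAL_COLUMNS = ("quantity", "true_duration_days")

#: stable column order for duration output files
DURATION_COLUMNS = (
    "patient_id",
    "fill_date",
    "drug_code",
    "gap_days",
    "cluster_id",
    "duration_days",
    "end_of_supply",
)


@dataclass(frozen=True)
class PrescriptionFill:
    """One dispensing event.

    ``quantity`` is the number of dispensed units (tablets etc.), used only
    by the researcher-defined-duration comparator.  ``true_duration_days``
    is simulator ground truth and is never consulted by the estimator.
    """

    patient_id: str
    day: int
    drug_code: str = ""
    quantity: Optional[int] = None
    true_duration_days: Optional[int] = None

    def __post_init__(self) -> None:
        if self.quantity is not None and self.quantity < 1:
            raise ValueError(f"quantity must be >= 1, got {self.quantity}")
        if self.true_duration_days is not None and self.true_duration_days < 1:
            raise ValueError(f"true_duration_days must be >= 1, got {self.true_duration_days}")


@dataclass(frozen=True)
class TruthEvent:
    """An externally supplied date on which a patient is known exposed."""

    patient_id: str
    day: int


@dataclass(frozen=True)
class Cohort:
    """Validated fills for one drug within an observational window.

    ``fills`` is a DataFrame with columns patient_id (str), day (int),
    drug_code (str), quantity (nullable), true_duration_days (nullable),
    sorted by (patient_id, day).  ``window_days`` is the half-open window
    length: valid fill days are ``0 <= day < window_days``.
    """

    fills: pd.DataFrame
    window_start: _dt.date
    window_days: int

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValueError("window must span at least one day")

    @property
    def n_patients(self) -> int:
        return int(self.fills["patient_id"].nunique())

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.fills["patient_id"].unique())

    def to_dates(self, days: Sequence[int]) -> list[_dt.date]:
        return [self.window_start + _dt.timedelta(days=int(d)) for d in days]


def _normalise_fills(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["drug_code"] = df.get("drug_code", "").astype(str)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.sort_values(["patient_id", "day"], kind="mergesort").reset_index(drop=True)
    cols = ["patient_id", "day", "drug_code", "quantity", "true_duration_days"]
    return df[cols]


def cohort_from_days(
    rows: Sequence[tuple],
    window_days: Optional[int] = None,
    window_start: _dt.date = _dt.date(2010, 1, 1),
) -> Cohort:
    """Build a Cohort from ``(patient_id, day[, duration[, quantity]])`` tuples.

    Convenience constructor used by the simulator and by tests; the nominal
    ``window_start`` only matters when writing calendar dates.
    """
    recs = []
    for row in rows:
        pid, day = row[0], int(row[1])
        dur = int(row[2]) if len(row) > 2 and row[2] is not None else np.nan
        qty = int(row[3]) if len(row) > 3 and row[3] is not None else np.nan
        recs.append((str(pid), day, "SIM", qty, dur))
    df = pd.DataFrame(recs, columns=["patient_id", "day", "drug_code", "quantity", "true_duration_days"])
    if window_days is None:
        window_days = int(df["day"].max()) + 1 if len(df) else 1
    return Cohort(fills=_normalise_fills(df), window_start=window_start, window_days=window_days)


def read_fills(
    path: str | Path,
    date_format: str = "%Y-%m-%d",
    window_start: Optional[_dt.date] = None,
    window_end: Optional[_dt.date] = None,
) -> Cohort:
    """Read a fills CSV into a Cohort.

    The window defaults to ``[min fill date, max fill date]`` (both
    inclusive, hence ``window_days = span + 1``) unless overridden.

    Raises
    ------
    ValueError
        If a required column is missing, or a date fails to parse (the
        error names the offending file row, counting the header as row 1).
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "drug_code": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    parsed = pd.to_datetime(df["fill_date"], format=date_format, errors="coerce")
    bad = parsed.isna() & df["fill_date"].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(
            f"unparseable fill_date {df.loc[bad.idxmax(), 'fill_date']!r} on row {row} of {path}"
        )
    if parsed.isna().any():
        row = int(parsed.isna().idxmax()) + 2
        raise ValueError(f"missing fill_date on row {row} of {path}")
    dates = parsed.dt.date
    start = window_start if window_start is not None else dates.min()
    end = window_end if window_end is not None else dates.max()
    if end < start:
        raise ValueError("window_end precedes window_start")
    df = df.assign(day=[(d - start).days for d in dates])
    return Cohort(
        fills=_normalise_fills(df),
        window_start=start,
        window_days=(end - start).days + 1,
    )


def validate_cohort(cohort: Cohort) -> Cohort:
    """Enforce cohort invariants; idempotent.

    Same-day duplicate fills of a patient are collapsed to one row with
    quantities summed (registers occasionally record split dispensings);
    fills outside the observational window are dropped with a logged count.

    Raises
    ------
    ValueError
        If no fill remains inside the window.
    """
    df = cohort.fills
    inside = (df["day"] >= 0) & (df["day"] < cohort.window_days)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("validate_cohort: dropped %d fill(s) outside the window", n_dropped)
    df = df[inside]
    if df.empty:
        raise ValueError("cohort is empty after window filtering")
    agg = df.groupby(["patient_id", "day"], as_index=False, sort=True).agg(
        drug_code=("drug_code", "first"),
        quantity=("quantity", lambda s: s.sum(min_count=1)),
        true_duration_days=("true_duration_days", "first"),
    )
    return replace(cohort, fills=_normalise_fills(agg))


def write_durations(assigned: pd.DataFrame, path: str | Path, window_start: _dt.date) -> None:
    """Write an assigned-durations table as CSV with ISO-8601 dates.

    ``assigned`` carries integer day offsets (``day``, ``end_day``) plus
    ``gap_days`` (missing on each patient's last fill), ``cluster_id`` and
    ``duration_days``; days are converted to calendar dates on output.
    """
    out = assigned.copy()
    out["fill_date"] = [
        (window_start + _dt.timedelta(days=int(d))).isoformat() for d in out["day"]
    ]
    out["end_of_supply"] = [
        (window_start + _dt.timedelta(days=int(d))).isoformat() for d in out["end_day"]
    ]
    cols = [c for c in DURATION_COLUMNS if c in out.columns or c in ("fill_date", "end_of_supply")]
    out[cols].to_csv(path, index=False)


def read_truth_events(path: str | Path, window_start: _dt.date, date_format: str = "%Y-%m-%d") -> pd.DataFrame:
    """Read a ``patient_id,event_date`` CSV into day offsets."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    parsed = pd.to_datetime(df["event_date"], format=date_format, errors="coerce")
    if parsed.isna().any():
        row = int(parsed.isna().idxmax()) + 2
        raise ValueError(f"unparseable event_date on row {row} of {path}")
    return pd.DataFrame(
        {"patient_id": df["patient_id"].astype(str), "day": [(d.date() - window_start).days for d in parsed]}
    )
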