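"""Validation of estimated exposure status against known truth.

The core check: draw one uniformly random date per patient inside the
observational window and compare true exposure (from simulated durations)
with estimated exposure (from SEE or RDD durations) on that date.  Each
patient lands in one confusion-matrix cell — true/false positive/negative
— from which ten classification metrics are computed.  Duration error is
summarised as the absolute difference in days between true and assigned
durations, per cell and pooled.

Because most patients are exposed on most days, the matrix is heavily
imbalanced; `balanced_subsample` recomputes the metrics after
down-sampling, and `sensitivity_at_event_dates` mirrors the register-style
validation where only dates of known exposure (e.g. detectable plasma
concentrations) are available, so only sensitivity can be assessed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import Cohort
from .timeline import ExposureTimeline

logger = logging.getLogger(__name__)

CATEGORIES = ("TP", "FP", "FN", "TN")

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "balanced_accuracy",
    "kappa",
    "f1",
    "recall",
    "precision",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Per-individual exposure classification counts at the random dates."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_categories(cls, categories: Sequence[str]) -> "ConfusionMatrix":
        c = pd.Series(categories).value_counts()
        return cls(
            tp=int(c.get("TP", 0)),
            fp=int(c.get("FP", 0)),
            fn=int(c.get("FN", 0)),
            tn=int(c.get("TN", 0)),
        )


@dataclass
class EvaluationReport:
    """Confusion matrix, the ten metrics, and duration-error summaries."""

    matrix: ConfusionMatrix
    metrics: dict[str, float]
    misclassification_days: dict = field(default_factory=dict)


def draw_random_dates(cohort: Cohort, seed: int | np.random.Generator = 0) -> pd.Series:
    """One uniform random day per patient over the half-open window."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pids = cohort.patient_ids
    days = rng.integers(0, cohort.window_days, size=len(pids))
    return pd.Series(days, index=pd.Index(pids, name="patient_id"), name="day")


def classify_patients(
    true_timelines: Mapping[str, ExposureTimeline],
    est_timelines: Mapping[str, ExposureTimeline],
    dates: pd.Series,
) -> pd.Series:
    """Per-patient confusion-matrix category at each patient's date."""
    cats = {}
    for pid, day in dates.items():
        if pid not in true_timelines or pid not in est_timelines:
            raise ValueError(f"patient {pid} missing from a timeline")
        truth = true_timelines[pid].is_exposed(int(day))
        est = est_timelines[pid].is_exposed(int(day))
        cats[pid] = ("TP" if est else "FN") if truth else ("FP" if est else "TN")
    return pd.Series(cats, name="category")


def classify_random_dates(
    true_timelines: Mapping[str, ExposureTimeline],
    est_timelines: Mapping[str, ExposureTimeline],
    dates: pd.Series,
) -> ConfusionMatrix:
    """Tally the confusion matrix over all patients."""
    return ConfusionMatrix.from_categories(classify_patients(true_timelines, est_timelines, dates))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(matrix: ConfusionMatrix) -> dict[str, float]:
    """The ten classification metrics; zero-denominator ratios are NaN."""
    tp, fp, fn, tn = matrix.tp, matrix.fp, matrix.fn, matrix.tn
    n = matrix.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    acc = (tp + tn) / n
    bal = (sens + spec) / 2
    f1 = _safe_div(2 * ppv * sens, ppv + sens) if not (math.isnan(ppv) or math.isnan(sens)) else float("nan")
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = _safe_div(p_o - p_e, 1 - p_e) if p_e < 1 else float("nan")
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "balanced_accuracy": bal,
        "kappa": kappa,
        "f1": f1,
        "recall": sens,
        "precision": ppv,
    }


def _summary(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {"n": 0, "median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    return {
        "n": int(values.size),
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
    }


def misclassification_days(
    true_fills: pd.DataFrame,
    assigned: pd.DataFrame,
    categories: pd.Series,
    pooled_categories: tuple[str, ...] = ("TP", "TN", "FN"),
) -> dict:
    """|true duration − assigned duration| per fill, summarised per cell.

    Fills are matched 1:1 on (patient_id, day).  Returns per-category and
    pooled medians/IQRs; the default pool follows the headline summary
    (true positives, true negatives and false negatives).
    """
    left = true_fills[["patient_id", "day", "true_duration_days"]]
    merged = left.merge(assigned[["patient_id", "day", "duration_days"]], on=["patient_id", "day"], how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("true and assigned fills do not match 1:1")
    if merged["true_duration_days"].isna().any():
        raise ValueError("true_duration_days missing on some fills")
    merged["abs_error"] = (merged["true_duration_days"] - merged["duration_days"]).abs()
    merged["category"] = merged["patient_id"].map(categories)

    out: dict = {}
    for cat in CATEGORIES:
        vals = merged.loc[merged["category"] == cat, "abs_error"].to_numpy(dtype=float)
        out[cat] = _summary(vals)
    pooled = merged.loc[merged["category"].isin(pooled_categories), "abs_error"].to_numpy(dtype=float)
    out["pooled"] = _summary(pooled)
    out["pooled_categories"] = list(pooled_categories)
    out["all"] = _summary(merged["abs_error"].to_numpy(dtype=float))
    return out


def balanced_subsample(
    categories: pd.Series,
    seed: int | np.random.Generator = 0,
    mode: str = "truth_class",
) -> tuple[ConfusionMatrix, dict[str, float], pd.Series]:
    """Recompute the metrics on a class-balanced random subsample.

    mode="truth_class" (default): the truly exposed individuals (TP and FN
    cells together) are down-sampled uniformly to the size of the truly
    unexposed class (TN + FP).  This is the down-sampling that changes the
    predictive values: shrinking FN alongside TP raises NPV when the
    exposed class dominates.

    mode="tp_only": only the TP cell is down-sampled, to the size of the
    largest other cell.  This balances raw cell counts but leaves
    NPV = TN/(TN+FN) untouched by construction.

    If the data are not imbalanced in the required direction, the input is
    returned unchanged (with a log note).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cats = categories.copy()
    if mode == "truth_class":
        exposed = cats.index[cats.isin(["TP", "FN"])]
        n_unexposed = int(cats.isin(["TN", "FP"]).sum())
        if len(exposed) <= n_unexposed or n_unexposed == 0:
            logger.info("balanced_subsample: no exposed-class excess; returning unchanged")
            m = ConfusionMatrix.from_categories(cats)
            return m, compute_metrics(m), cats
        keep = rng.choice(len(exposed), size=n_unexposed, replace=False)
        kept = set(exposed[sorted(keep)])
        balanced = cats[cats.index.isin(kept) | cats.isin(["TN", "FP"])]
    elif mode == "tp_only":
        tp_ids = cats.index[cats == "TP"]
        target = int(cats[cats != "TP"].value_counts().max()) if (cats != "TP").any() else 0
        if len(tp_ids) <= target or target == 0:
            logger.info("balanced_subsample: TP cell not in excess; returning unchanged")
            m = ConfusionMatrix.from_categories(cats)
            return m, compute_metrics(m), cats
        keep = rng.choice(len(tp_ids), size=target, replace=False)
        kept = set(tp_ids[sorted(keep)])
        balanced = cats[cats.index.isin(kept) | (cats != "TP")]
    else:
        raise ValueError(f"unknown balancing mode {mode!r}")
    m = ConfusionMatrix.from_categories(balanced)
    return m, compute_metrics(m), balanced


def sensitivity_at_event_dates(
    est_timelines: Mapping[str, ExposureTimeline],
    events: pd.DataFrame,
    tolerance_days: int = 0,
) -> float:
    """Fraction of known-exposure events the estimated timelines detect.

    An event is detected if any estimated exposure interval intersects
    ``[event_day − tolerance, event_day + tolerance]`` (inclusive); the
    tolerance stands in for drug half-life slack around, e.g., a plasma
    measurement.
    """
    if events.empty:
        raise ValueError("no truth events supplied")
    if tolerance_days < 0:
        raise ValueError("tolerance_days must be >= 0")
    detected = 0
    for pid, day in zip(events["patient_id"], events["day"]):
        tl = est_timelines.get(str(pid))
        if tl is None:
            raise ValueError(f"patient {pid} has no estimated timeline")
        lo, hi = int(day) - tolerance_days, int(day) + tolerance_days
        if any(s <= hi and e - 1 >= lo for s, e in tl.intervals):
            detected += 1
    return detected / len(events)


def draw_truth_events(
    true_timelines: Mapping[str, ExposureTimeline],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """One synthetic truth event per patient, uniform over their truly
    exposed days (patients with no exposed day are skipped).

    Emulates register-style validation data where each patient contributes
    a measurement taken while demonstrably exposed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for pid in sorted(true_timelines):
        tl = true_timelines[pid]
        total = tl.total_covered
        if total == 0:
            continue
        r = int(rng.integers(total))
        for s, e in tl.intervals:
            if r < e - s:
                rows.append((pid, s + r))
                break
            r -= e - s
    return pd.DataFrame(rows, columns=["patient_id", "day"])


def evaluate_cohort(
    true_timelines: Mapping[str, ExposureTimeline],
    est_timelines: Mapping[str, ExposureTimeline],
    dates: pd.Series,
    true_fills: Optional[pd.DataFrame] = None,
    assigned: Optional[pd.DataFrame] = None,
) -> tuple[EvaluationReport, pd.Series]:
    """Full random-date evaluation; returns the report and the per-patient
    categories (needed for balancing and duration-error summaries)."""
    cats = classify_patients(true_timelines, est_timelines, dates)
    matrix = ConfusionMatrix.from_categories(cats)
    report = EvaluationReport(matrix=matrix, metrics=compute_metrics(matrix))
    if true_fills is not None and assigned is not None:
        report.misclassification_days = misclassification_days(true_fills, assigned, cats)
    return report, cats
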