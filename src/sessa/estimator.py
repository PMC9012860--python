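"""The Sessa Empirical Estimator (SEE).

A data-driven estimator of prescription durations when the daily dose is
unknown.  It assumes the dispensed amount is consumed between consecutive
fills, so the duration of a fill is informed by the refill gap (the
"temporal distance" to the next fill).  The algorithm:

1. Pool the refill gaps of all patients and keep only the lower 80% of
   their empirical CDF, discarding the artificially long gaps created by
   stoppers/re-starters and hospitalisation blackouts.
2. Keep one randomly chosen retained gap per patient, so frequent fillers
   do not dominate the estimate.
3. Standardise the sampled gaps (zero mean, unit sample SD) and cluster
   them with k-means; the number of clusters K is chosen by maximising the
   average silhouette width over a K range.
4. Use each cluster's median gap (on the original day scale) as the
   estimated duration of every prescription assigned to that cluster.
5. End of supply = fill date + estimated duration.

Durations for each patient's final fill (which has no following gap) are
inherited from the patient's most recent assigned fill, falling back to
the overall median of the cluster medians — a rule the procedure needs in
order to answer exposure queries at arbitrary dates.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score

from .data import Cohort
from .timeline import ExposureTimeline, _round_half_away


@dataclass(frozen=True)
class SeeConfig:
    """Estimator settings.

    ``ecdf_retention`` is the fraction of the gap ECDF kept in step 1
    (default 0.8).  ``k_min``/``k_max`` bound the silhouette search for K;
    ``n_restarts`` is the number of random k-means initialisations per K.
    """

    ecdf_retention: float = 0.8
    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ecdf_retention <= 1.0):
            raise ValueError("ecdf_retention must be in (0, 1]")
        if self.k_min < 2 or self.k_min > self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class SeeModel:
    """A fitted SEE: everything needed to assign durations to new fills."""

    retention_cutoff_days: float
    standardization_mean: float
    standardization_sd: float
    k_selected: int
    centers_std: tuple[float, ...]          # ascending, standardized scale
    median_duration_days: tuple[float, ...]  # one per cluster, day scale
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    sampled_gaps: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        meds = self.median_duration_days
        if any(b < a for a, b in zip(meds, meds[1:])):
            raise ValueError("cluster medians must be non-decreasing with center order")
        if any(m > self.retention_cutoff_days for m in meds):
            raise ValueError("cluster medians cannot exceed the retention cutoff")

    def to_json(self, path) -> None:
        payload = {
            "retention_cutoff_days": self.retention_cutoff_days,
            "standardization_mean": self.standardization_mean,
            "standardization_sd": self.standardization_sd,
            "k_selected": self.k_selected,
            "centers_std": list(self.centers_std),
            "median_duration_days": list(self.median_duration_days),
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SeeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            retention_cutoff_days=d["retention_cutoff_days"],
            standardization_mean=d["standardization_mean"],
            standardization_sd=d["standardization_sd"],
            k_selected=d["k_selected"],
            centers_std=tuple(d["centers_std"]),
            median_duration_days=tuple(d["median_duration_days"]),
            silhouette_by_k={int(k): v for k, v in d["silhouette_by_k"].items()},
        )


def compute_refill_gaps(cohort: Cohort) -> pd.DataFrame:
    """Gaps (days) between consecutive same-patient fills.

    Returns a DataFrame with columns ``patient_id``, ``fill_index`` (ordinal
    of the earlier fill within the patient, 0-based) and ``gap_days``.
    Single-fill patients contribute nothing.
    """
    df = cohort.fills
    days = df["day"].to_numpy()
    pids = df["patient_id"].to_numpy()
    nxt_same = pids[1:] == pids[:-1]
    gaps = days[1:] - days[:-1]
    idx_in_patient = np.zeros(len(df), dtype=int)
    for i in range(1, len(df)):
        idx_in_patient[i] = idx_in_patient[i - 1] + 1 if pids[i] == pids[i - 1] else 0
    out = pd.DataFrame(
        {
            "patient_id": pids[:-1][nxt_same],
            "fill_index": idx_in_patient[:-1][nxt_same],
            "gap_days": gaps[nxt_same].astype(int),
        }
    )
    return out.reset_index(drop=True)


def trim_ecdf(gaps: pd.DataFrame, retention: float = 0.8) -> tuple[pd.DataFrame, float]:
    """Keep the lower ``retention`` fraction of the gap ECDF.

    The cutoff is the smallest observed gap value whose ECDF is at least
    ``retention``; all gaps <= cutoff are retained (ties included), so the
    retained fraction is always >= ``retention``.
    """
    if gaps.empty:
        raise ValueError("no refill gaps to trim")
    values = np.sort(gaps["gap_days"].to_numpy())
    n = len(values)
    k = int(math.ceil(retention * n))  # smallest rank with ECDF >= retention
    cutoff = float(values[k - 1])
    retained = gaps[gaps["gap_days"] <= cutoff].reset_index(drop=True)
    return retained, cutoff


def sample_random_pairs(retained: pd.DataFrame, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """One uniformly chosen retained gap per patient.

    Patients whose every gap exceeded the cutoff are simply absent.
    Deterministic given the seed; patients are processed in sorted order.
    """
    if retained.empty:
        raise ValueError("no retained gaps to sample from")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picks = []
    for pid, sub in retained.groupby("patient_id", sort=True):
        picks.append(sub.iloc[int(rng.integers(len(sub)))])
    return pd.DataFrame(picks).reset_index(drop=True)


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Center and scale to unit sample SD (n-1 denominator).

    Returns ``(standardized, mean, sd)``; ``sd == 0`` signals a degenerate
    (constant) input, which `fit_see` resolves with a one-cluster model.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardize needs at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return np.zeros_like(x), mean, 0.0
    return (x - mean) / sd, mean, sd


def select_k_silhouette(
    z: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    n_restarts: int = 50,
    seed: int = 0,
) -> tuple[int, dict[int, float], np.ndarray, np.ndarray]:
    """Fit k-means for each K and pick the K with the highest average
    silhouette width (ties broken toward smaller K).

    Returns ``(k_selected, silhouette_by_k, labels, centers)`` with
    clusters relabelled so centers are ascending.  The K range is capped
    at one less than the number of distinct values.
    """
    z = np.asarray(z, dtype=float)
    n_distinct = len(np.unique(z))
    k_hi = min(k_max, n_distinct - 1)
    if k_hi < k_min:
        raise ValueError("fewer distinct values than k_min; degenerate input")
    X = z.reshape(-1, 1)
    rng = np.random.default_rng(seed)
    sil_by_k: dict[int, float] = {}
    best: Optional[tuple[int, np.ndarray, np.ndarray]] = None
    best_sil = -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(k_min, k_hi + 1):
            km = KMeans(
                n_clusters=k,
                n_init=n_restarts,
                random_state=int(rng.integers(2**31)),
                algorithm="lloyd",
            ).fit(X)
            labels = km.labels_
            if len(np.unique(labels)) < 2:
                continue
            sil = float(silhouette_score(X, labels))
            sil_by_k[k] = sil
            if sil > best_sil:  # strict: ties keep the smaller K
                best_sil = sil
                best = (k, labels.copy(), km.cluster_centers_.ravel().copy())
    if best is None:
        raise ValueError("silhouette selection failed for every K")
    k_sel, labels, centers = best
    order = np.argsort(centers)
    relabel = np.empty_like(order)
    relabel[order] = np.arange(len(order))
    return k_sel, sil_by_k, relabel[labels], centers[order]


def fit_see(cohort: Cohort, config: SeeConfig = SeeConfig()) -> SeeModel:
    """Fit the estimator on a cohort (steps 1-4).

    Degenerate cohorts — sampled gaps with zero variance or fewer distinct
    values than ``k_min`` — yield a one-cluster model whose single median
    is the median sampled gap.
    """
    gaps = compute_refill_gaps(cohort)
    if gaps.empty:
        raise ValueError("no patient has two or more fills; cannot fit")
    retained, cutoff = trim_ecdf(gaps, config.ecdf_retention)
    root = np.random.SeedSequence(config.seed)
    pair_seq, kmeans_seq = root.spawn(2)
    sampled = sample_random_pairs(retained, np.random.default_rng(pair_seq))
    values = sampled["gap_days"].to_numpy(dtype=float)

    n_distinct = len(np.unique(values))
    if values.size < 2 or n_distinct <= config.k_min:
        median = round(float(np.median(values)), 2)
        return SeeModel(
            retention_cutoff_days=cutoff,
            standardization_mean=float(values.mean()),
            standardization_sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
            k_selected=1,
            centers_std=(0.0,),
            median_duration_days=(median,),
            silhouette_by_k={},
            sampled_gaps=sampled,
        )

    z, mean, sd = standardize(values)
    if sd == 0.0:
        median = round(float(np.median(values)), 2)
        return SeeModel(
            retention_cutoff_days=cutoff,
            standardization_mean=mean,
            standardization_sd=0.0,
            k_selected=1,
            centers_std=(0.0,),
            median_duration_days=(median,),
            silhouette_by_k={},
            sampled_gaps=sampled,
        )
    kmeans_seed = int(kmeans_seq.generate_state(1)[0] % (2**31))
    k_sel, sil_by_k, labels, centers = select_k_silhouette(
        z, config.k_min, config.k_max, config.n_restarts, kmeans_seed
    )
    medians = tuple(
        round(float(np.median(values[labels == c])), 2) for c in range(k_sel)
    )
    return SeeModel(
        retention_cutoff_days=cutoff,
        standardization_mean=mean,
        standardization_sd=sd,
        k_selected=k_sel,
        centers_std=tuple(float(c) for c in centers),
        median_duration_days=medians,
        silhouette_by_k=sil_by_k,
        sampled_gaps=sampled,
    )


def _nearest_cluster(z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment; equidistant points go to the smaller center."""
    d = np.abs(z[:, None] - centers[None, :])
    return d.argmin(axis=1)  # argmin takes the first (= smaller center) on ties


def assign_durations(cohort: Cohort, model: SeeModel) -> pd.DataFrame:
    """Assign a duration and end of supply to every fill (step 5).

    Fills followed by another fill are assigned by their gap's nearest
    cluster center (gaps above the retention cutoff included); each
    patient's last fill inherits the cluster of the patient's most recent
    assigned fill, or — for patients with no assigned gap — the overall
    median of the cluster medians, rounded to the nearest day.

    Returns a DataFrame with columns patient_id, day, drug_code, gap_days,
    cluster_id, duration_days, end_day.
    """
    if model.k_selected < 1:
        raise ValueError("model is not fitted")
    df = cohort.fills.copy().reset_index(drop=True)
    days = df["day"].to_numpy()
    pids = df["patient_id"].to_numpy()
    same = np.r_[pids[1:] == pids[:-1], False]
    gap = np.full(len(df), np.nan)
    gap[:-1][same[:-1]] = (days[1:] - days[:-1])[same[:-1]]

    centers = np.asarray(model.centers_std)
    medians = np.asarray(model.median_duration_days)
    cluster = np.full(len(df), -1)
    has_gap = ~np.isnan(gap)
    if model.k_selected == 1 or model.standardization_sd == 0.0:
        cluster[has_gap] = 0
    else:
        z = (gap[has_gap] - model.standardization_mean) / model.standardization_sd
        cluster[has_gap] = _nearest_cluster(z, centers)

    duration = np.full(len(df), np.nan)
    duration[has_gap] = medians[cluster[has_gap]]

    fallback = float(_round_half_away(float(np.median(medians))))
    cluster_col = np.full(len(df), np.nan)
    cluster_col[has_gap] = cluster[has_gap]
    # last fills inherit the patient's most recent assigned cluster
    for pid, idx in pd.Series(range(len(df))).groupby(pids):
        ii = idx.to_numpy()
        last = ii[-1]
        if np.isnan(duration[last]):
            prev_assigned = ii[has_gap[ii]]
            if len(prev_assigned):
                c = cluster[prev_assigned[-1]]
                duration[last] = medians[c]
                cluster_col[last] = c
            else:
                duration[last] = fallback

    end_day = np.array([int(d) + _round_half_away(float(x)) for d, x in zip(days, duration)])
    out = df[["patient_id", "day", "drug_code"]].copy()
    out["gap_days"] = gap
    out["cluster_id"] = cluster_col
    out["duration_days"] = duration
    out["end_day"] = end_day
    return out


def build_exposure_timeline(assigned: pd.DataFrame) -> dict[str, ExposureTimeline]:
    """Per-patient merged exposure timelines from assigned durations."""
    out: dict[str, ExposureTimeline] = {}
    for pid, sub in assigned.groupby("patient_id", sort=True):
        ivs = [(int(d), int(e)) for d, e in zip(sub["day"], sub["end_day"])]
        out[str(pid)] = ExposureTimeline.from_intervals(str(pid), ivs)
    return out
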