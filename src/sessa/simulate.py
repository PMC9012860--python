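"""Synthetic prescription-fill histories with known ("true") durations.

The generator emulates a single-drug register extract: every patient
starts with a 30-day fill on day 0 and refills over a two-year window,
with refill durations drawn uniformly from {1, 2, 3} months (30/60/90
days).  Refill timing follows one of six adherence trajectories observed
in real-world antihypertensive cohorts:

1. ``high`` — ~95% of days covered; refills almost immediately at the end
   of each supply.
2. ``medium`` — per-patient target adherence drawn from 50–90%; refill
   delays are uniform with mean matching the target.
3. ``declining`` — target adherence falls linearly from 95% to 40% over
   the window.
4. ``intermittent`` — alternating 90-day phases of high (95%) and low
   (50%) adherence.
5. ``partial_dropoff`` — high adherence until a change point (uniform on
   days 180–540), after which adherence partially drops off: refilling
   continues with a per-patient target adherence drawn from 50–90%.
6. ``non_persistent`` — one or two refills after the initial fill, then
   none.

No carry-over is modelled: each fill covers ``[fill, fill + duration)``
and unused supply is never credited forward, i.e. the patient is assumed
to have consumed a fill before starting the next one.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import Cohort, _normalise_fills
from .timeline import ExposureTimeline, merge_intervals

GROUP_LABELS = (
    "high",
    "medium",
    "declining",
    "intermittent",
    "partial_dropoff",
    "non_persistent",
)

# Default mix of trajectory groups (fractions of the cohort, renormalised):
# the realized composition of the reference simulation study.
DEFAULT_GROUP_PROPORTIONS = (0.100, 0.093, 0.236, 0.093, 0.379, 0.099)

_HIGH_ADHERENCE = 0.95
_LOW_ADHERENCE = 0.50
_DECLINE_FLOOR = 0.40
_PHASE_DAYS = 90
_DROPOFF_LO, _DROPOFF_HI = 180, 540


@dataclass(frozen=True)
class TrajectoryGroupSpec:
    """One adherence-trajectory group and its share of the cohort."""

    group_id: int
    label: str
    target_proportion: float
    adherence_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            raise ValueError(f"unknown trajectory label {self.label!r}")
        if not (1 <= self.group_id <= 6):
            raise ValueError("group_id must be in 1..6")


def default_groups(proportions: Sequence[float] = DEFAULT_GROUP_PROPORTIONS) -> list[TrajectoryGroupSpec]:
    props = np.asarray(proportions, dtype=float)
    if props.shape != (6,) or (props < 0).any() or props.sum() <= 0:
        raise ValueError("group_proportions must be 6 nonnegative fractions")
    props = props / props.sum()
    return [
        TrajectoryGroupSpec(group_id=i + 1, label=lab, target_proportion=float(p))
        for i, (lab, p) in enumerate(zip(GROUP_LABELS, props))
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated cohort.

    Defaults reproduce the reference design: 1000 patients, 730-day
    window, an initial 30-day fill for everyone, refills of 30/60/90 days,
    and the six-group mix above.  ``quantity_noise_days`` perturbs the
    emitted ``quantity`` (one unit per day) so the researcher-defined
    comparator is not trivially exact.
    """

    n_patients: int = 1000
    window_days: int = 730
    initial_duration_days: int = 30
    refill_duration_choices_days: tuple[int, ...] = (30, 60, 90)
    group_proportions: tuple[float, ...] = DEFAULT_GROUP_PROPORTIONS
    seed: int = 0
    with_quantity: bool = True
    quantity_noise_days: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.window_days < self.initial_duration_days:
            raise ValueError("window_days must be >= initial_duration_days")
        if any(d < 1 for d in self.refill_duration_choices_days):
            raise ValueError("every refill duration choice must be >= 1")
        props = np.asarray(self.group_proportions, dtype=float)
        if props.shape != (6,) or (props < 0).any() or props.sum() <= 0:
            raise ValueError("group_proportions must be 6 nonnegative fractions")


def _delay_high(duration: int, rng: np.random.Generator) -> int:
    """Delay after a supply of `duration` days in the high-adherence regime."""
    return int(round(rng.uniform(0.0, duration * (1.0 / _HIGH_ADHERENCE - 1.0))))


def _delay_target(duration: int, adherence: float, rng: np.random.Generator) -> int:
    """Uniform delay whose mean realises the target adherence fraction."""
    return int(round(rng.uniform(0.0, 2.0 * duration * (1.0 / adherence - 1.0))))


def simulate_patient(
    group: TrajectoryGroupSpec | str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Simulate one patient's fill history as ``(day, true_duration)`` pairs.

    The first fill is on day 0 with the initial duration; every patient
    gets at least one refill.  Deterministic given ``rng``'s state.
    """
    label = group.label if isinstance(group, TrajectoryGroupSpec) else str(group)
    if label not in GROUP_LABELS:
        raise ValueError(f"unknown trajectory label {label!r}")
    W = config.window_days
    choices = np.asarray(config.refill_duration_choices_days)

    if label == "medium":
        target = rng.uniform(_LOW_ADHERENCE, 0.90)
    elif label == "partial_dropoff":
        change_point = rng.uniform(_DROPOFF_LO, _DROPOFF_HI)
        post_target: Optional[float] = None
    elif label == "non_persistent":
        max_refills = int(rng.integers(1, 3))  # 1 or 2, equal probability

    fills: list[tuple[int, int]] = [(0, config.initial_duration_days)]
    while True:
        day, dur = fills[-1]
        supply_end = day + dur
        if label == "non_persistent" and len(fills) - 1 >= max_refills:
            break
        if label == "high" or label == "non_persistent":
            delay = _delay_high(dur, rng)
        elif label == "medium":
            delay = _delay_target(dur, target, rng)
        elif label == "declining":
            frac = min(supply_end / W, 1.0)
            current = _HIGH_ADHERENCE - (_HIGH_ADHERENCE - _DECLINE_FLOOR) * frac
            delay = _delay_target(dur, current, rng)
        elif label == "intermittent":
            phase_high = (supply_end // _PHASE_DAYS) % 2 == 0
            adherence = _HIGH_ADHERENCE if phase_high else _LOW_ADHERENCE
            delay = _delay_target(dur, adherence, rng)
        else:  # partial_dropoff
            if supply_end < change_point:
                delay = _delay_high(dur, rng)
            else:
                if post_target is None:
                    post_target = rng.uniform(_LOW_ADHERENCE, 0.90)
                delay = _delay_target(dur, post_target, rng)
        next_day = supply_end + delay
        if next_day >= W:
            if len(fills) == 1:
                # the design guarantees a subsequent fill; only very short
                # windows can hit this, so clamp the refill into the window
                next_day = W - 1
            else:
                break
        fills.append((next_day, int(rng.choice(choices))))
        if label == "non_persistent" and len(fills) - 1 >= max_refills:
            break
    return fills


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a full cohort.

    Returns the Cohort (fills carry ``true_duration_days`` and, when
    configured, ``quantity``) and a per-patient group-assignment table
    with columns ``patient_id``, ``group_id``, ``label``.
    """
    groups = default_groups(config.group_proportions)
    props = np.array([g.target_proportion for g in groups])
    root = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    assignments = assign_rng.choice(6, size=config.n_patients, p=props)
    patient_seeds = root.spawn(config.n_patients)

    width = max(4, len(str(config.n_patients)))
    recs = []
    group_rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        g = groups[assignments[i]]
        rng = np.random.default_rng(patient_seeds[i])
        history = simulate_patient(g, config, rng)
        for day, dur in history:
            if config.with_quantity:
                if config.quantity_noise_days > 0:
                    noise = int(rng.integers(-config.quantity_noise_days, config.quantity_noise_days + 1))
                else:
                    noise = 0
                qty = max(1, dur + noise)
            else:
                qty = np.nan
            recs.append((pid, day, "SIM", qty, dur))
        group_rows.append((pid, g.group_id, g.label))

    fills = pd.DataFrame(recs, columns=["patient_id", "day", "drug_code", "quantity", "true_duration_days"])
    cohort = Cohort(
        fills=_normalise_fills(fills),
        window_start=_dt.date(2010, 1, 1),
        window_days=config.window_days,
    )
    groups_df = pd.DataFrame(group_rows, columns=["patient_id", "group_id", "label"])
    return cohort, groups_df


def compute_true_exposure(fills: pd.DataFrame | Sequence[tuple[int, int]], patient_id: str = "") -> ExposureTimeline:
    """True exposure timeline for one patient: union of [day, day + true duration).

    Accepts either a fills DataFrame slice (columns ``day``,
    ``true_duration_days``) or a sequence of ``(day, duration)`` pairs.
    """
    if isinstance(fills, pd.DataFrame):
        if fills["true_duration_days"].isna().any():
            raise ValueError("true_duration_days missing on some fills")
        pairs = list(zip(fills["day"], fills["true_duration_days"]))
        if not patient_id and len(fills):
            patient_id = str(fills["patient_id"].iloc[0])
    else:
        pairs = list(fills)
        if any(d is None for _, d in pairs):
            raise ValueError("true_duration_days missing on some fills")
    return ExposureTimeline.from_intervals(patient_id, [(int(d), int(d) + int(t)) for d, t in pairs])


def true_exposure_timelines(cohort: Cohort) -> dict[str, ExposureTimeline]:
    """True exposure timelines for every patient in a simulated cohort."""
    if cohort.fills["true_duration_days"].isna().any():
        raise ValueError("cohort lacks true_duration_days; not a simulated cohort?")
    out = {}
    for pid, sub in cohort.fills.groupby("patient_id", sort=True):
        out[str(pid)] = compute_true_exposure(sub, str(pid))
    return out


def stretched_exposure_timelines(cohort: Cohort) -> dict[str, ExposureTimeline]:
    """True exposure under the dose-stretching consumption assumption.

    The dispensed amount is taken to be consumed over the whole interval
    to the next fill — the patient stays exposed across the refill delay
    (e.g. by taking less than the nominal daily dose), and the previous
    supply is finished exactly when the next prescription is filled.
    Each non-final fill therefore covers ``[fill, next fill)``; the final
    fill covers its nominal ``[fill, fill + true_duration)``.  This is
    the truth convention used for exposure-status evaluation; the
    supply-based `true_exposure_timelines` (exposure ends at
    fill + duration, refill delays uncovered) is what CMA-style
    availability summaries use.
    """
    if cohort.fills["true_duration_days"].isna().any():
        raise ValueError("cohort lacks true_duration_days; not a simulated cohort?")
    out: dict[str, ExposureTimeline] = {}
    for pid, sub in cohort.fills.groupby("patient_id", sort=True):
        days = sub["day"].to_numpy()
        durs = sub["true_duration_days"].to_numpy()
        ivs = [(int(a), int(b)) for a, b in zip(days[:-1], days[1:])]
        ivs.append((int(days[-1]), int(days[-1]) + int(durs[-1])))
        out[str(pid)] = ExposureTimeline.from_intervals(str(pid), ivs)
    return out


def compute_cma(
    fills: pd.DataFrame | Sequence[tuple[int, int]],
    window: tuple[int, int],
) -> float:
    """Continuous multiple-interval measure of medication availability.

    Fraction of the half-open window covered by the union of true-duration
    exposure intervals; in [0, 1].
    """
    start, end = int(window[0]), int(window[1])
    if end <= start:
        raise ValueError("empty observational window")
    tl = compute_true_exposure(fills)
    return tl.covered_days(start, end) / (end - start)
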